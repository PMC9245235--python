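{
 "case_id": "case05",
 "expected": {
  "expected_alert_types": [
   "contraindication"
  ],
  "expected_feasible": true,
  "planted_error_class": "contraindication"
 },
 "patient": {
  "age": 55,
  "conditions": [
   "severe_hepatic_disease"
  ],
  "sex": "M",
  "weight": 82.0
 },
 "prescription": [
  {
   "dose_amount": 20.0,
   "doses_per_day": 1,
   "drug": "ATORVASTATIN CALCIUM 20 MG"
  },
  {
   "dose_amount": 10.0,
   "doses_per_day": 1,
   "drug": "ENALAPRIL 10 MG"
  }
 ],
 "routine": {
  "busy_intervals": [],
  "meal_times": [
   {
    "label": "breakfast",
    "time": "07:30"
   },
   {
    "label": "lunch",
    "time": "12:30"
   },
   {
    "label": "dinner",
    "time": "19:30"
   }
  ],
  "sleep_time": "22:00",
  "wake_time": "07:00"
 }
}
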