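{
 "case_id": "case03",
 "expected": {
  "expected_alert_types": [],
  "expected_feasible": true,
  "planted_error_class": "night_routine"
 },
 "patient": {
  "age": 38,
  "conditions": [],
  "sex": "M",
  "weight": 75.0
 },
 "prescription": [
  {
   "dose_amount": 10.0,
   "doses_per_day": 1,
   "drug": "ENALAPRIL 10 MG"
  },
  {
   "dose_amount": 500.0,
   "doses_per_day": 3,
   "drug": "PARACETAMOL 500 MG"
  }
 ],
 "routine": {
  "busy_intervals": [
   {
    "end": "06:00",
    "label": "night shift",
    "start": "22:00"
   }
  ],
  "meal_times": [
   {
    "label": "breakfast",
    "time": "15:00"
   },
   {
    "label": "lunch",
    "time": "21:00"
   },
   {
    "label": "dinner",
    "time": "06:30"
   }
  ],
  "sleep_time": "07:30",
  "wake_time": "14:30"
 }
}
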