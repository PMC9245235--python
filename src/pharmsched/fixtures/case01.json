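{
 "case_id": "case01",
 "expected": {
  "expected_alert_types": [
   "nu_interaction"
  ],
  "expected_feasible": true,
  "planted_error_class": "nu_pair"
 },
 "patient": {
  "age": 68,
  "conditions": [],
  "sex": "F",
  "weight": 70.0
 },
 "prescription": [
  {
   "dose_amount": 500.0,
   "doses_per_day": 1,
   "drug": "ASPIRIN 500 MG"
  },
  {
   "dose_amount": 2.5,
   "doses_per_day": 1,
   "drug": "WARFARIN 2.5 MG"
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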