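{
 "case_id": "case10",
 "expected": {
  "expected_alert_types": [
   "observation"
  ],
  "expected_feasible": true,
  "planted_error_class": "specific_guidelines"
 },
 "patient": {
  "age": 67,
  "conditions": [],
  "sex": "F",
  "weight": 58.0
 },
 "prescription": [
  {
   "dose_amount": 70.0,
   "doses_per_day": 1,
   "drug": "ALENDRONATE SODIUM 70 MG"
  },
  {
   "dose_amount": 50.0,
   "doses_per_day": 1,
   "drug": "LEVOTHYROXINE 50 MCG"
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
  "wake_time": "06:00"
 }
}
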