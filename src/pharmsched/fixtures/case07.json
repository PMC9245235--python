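{
 "case_id": "case07",
 "expected": {
  "expected_alert_types": [
   "food_relation"
  ],
  "expected_feasible": true,
  "planted_error_class": "food_relation"
 },
 "patient": {
  "age": 35,
  "conditions": [],
  "sex": "F",
  "weight": 65.0
 },
 "prescription": [
  {
   "dose_amount": 20.0,
   "doses_per_day": 1,
   "drug": "OMEPRAZOLE 20 MG"
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
  "wake_time": "06:30"
 }
}
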