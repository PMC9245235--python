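{
 "case_id": "case08",
 "expected": {
  "expected_alert_types": [],
  "expected_feasible": true,
  "planted_error_class": "sleep_protection"
 },
 "patient": {
  "age": 6,
  "conditions": [],
  "sex": "F",
  "weight": 21.0
 },
 "prescription": [
  {
   "dose_amount": 250.0,
   "drug": "AMOXICILLIN SUSPENSION",
   "interval_hours": 8
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
    "time": "12:00"
   },
   {
    "label": "dinner",
    "time": "18:30"
   }
  ],
  "sleep_time": "21:00",
  "wake_time": "07:00"
 }
}
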