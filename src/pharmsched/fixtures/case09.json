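{
 "case_id": "case09",
 "expected": {
  "expected_alert_types": [
   "contraindication"
  ],
  "expected_feasible": true,
  "planted_error_class": "override_risk"
 },
 "patient": {
  "age": 28,
  "conditions": [
   {
    "code": "pregnancy",
    "qualifiers": {
     "weeks": 12
    }
   }
  ],
  "sex": "F",
  "weight": 62.0
 },
 "prescription": [
  {
   "clinical_override_note": "Epilepsy crisis prevention prioritized; risk accepted by clinical decision.",
   "dose_amount": 200.0,
   "doses_per_day": 2,
   "drug": "CARBAMAZEPINE 200 MG"
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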