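{
  "id": "4417",
  "site_ref": "3534",
  "comment": "Selby (eastern Colorado), Neotoma siteid 3534, collection unit 4417. Two dated analysis units with no recorded stratigraphic order plus one undated unit. Raw 14C ages/errors reconstructed by inverting the published calibrated control quantiles against IntCal20; SI-2877 matches its published value 11,710 +/- 150 14C BP.",
  "analysis_units": [
    {
      "id": "80053",
      "name": "AU 80053",
      "dates": [
        {"lab_id": "SI-2877", "age": 11710, "error": 150, "kind": "radiocarbon"},
        {"lab_id": "SI-3541", "age": 7902, "error": 156, "kind": "radiocarbon"}
      ]
    },
    {
      "id": "80054",
      "name": "AU 80054",
      "dates": []
    },
    {
      "id": "80055",
      "name": "AU 80055",
      "dates": [
        {"lab_id": "SI-5185", "age": 16606, "error": 331, "kind": "radiocarbon"},
        {"lab_id": "SI-5186", "age": 13805, "error": 525, "kind": "radiocarbon"}
      ]
    }
  ]
}
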