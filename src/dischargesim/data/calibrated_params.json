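{
  "note": "Calibrated free parameters of the default discharge-process graph (minutes). Produced by dischargesim.calibration (coordinate-descent simulated method of moments, common-random-number objective, 20-replication search evaluations with 100-replication verification) against the observed baseline mean/SD and the per-intervention reductions; regenerate with the 'dischargesim calibrate' subcommand.",
  "params": {
    "sigma_order": 20.0,
    "sigma_prep": 15.0,
    "porter_transport_mean": 7.5,
    "porter_file_mean": 4.5,
    "nurse_call_mean": 7.25,
    "pharmacist_arrival_mean": 5.0,
    "counseling_mean": 15.0,
    "clearance_mean": 5.5,
    "addon_prep_mean": 65.0,
    "addon_delivery_mean": 50.0,
    "equipment_sigma": 155.0,
    "supplies_sigma": 20.0,
    "narcotics_sigma": 6.0,
    "transport_counseling_mean": 17.0,
    "handover_mean": 8.0,
    "onfloor_delivery_mean": 25.0
  }
}
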