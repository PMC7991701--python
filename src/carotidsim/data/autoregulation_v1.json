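{
 "format": "carotidsim-autoregulation",
 "version": "1",
 "comment": "Lassen-type cerebral autoregulation anchors: perfusion pressure (mmHg) vs flow as fraction of baseline. Monotone PCHIP interpolation between anchors; linear continuation with the end slope above the last anchor. Synthetic stand-in curve with the canonical plateau 60-150 mmHg.",
 "plateau_mmhg": [60.0, 150.0],
 "P_mmhg":     [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 150.0, 160.0, 180.0, 200.0],
 "q_fraction": [0.0, 0.05, 0.15, 0.42, 0.75, 0.95, 1.0,  1.0,   1.03,  1.15,  1.30]
}
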