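{
  "comment": "Default elastic/intermediate/amyloid zone boundaries in the (G%, P%) plane. Each curve is a polyline of [g_pct, p_pct] vertices, flat beyond its last vertex. These are a calibration chosen so that well-characterised exemplar repeat units classify into their reported zones; edit to recalibrate.",
  "amyloid_intermediate": [[0, 20], [20, 0]],
  "intermediate_elastic": [[0, 40], [40, 0]]
}
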