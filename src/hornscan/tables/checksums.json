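{
  "table1": "06d497cfead0034e52ea500b1405e6548b34eff100fd6677c54d07ec478e795b",
  "table2": "fbe2b757a9b616e2be27734965464680b176ef36d72fa463f47e0c272cc0ad52",
  "table3": "d40691c3f3df2a80f2da4c40f32a5d22303c8628d6238ada9b07a2396bab8d7a",
  "table4": "ffd7a31a178bbbd590b0eac46c46cb733c1797a69844d6963d04a75f96ca2e8d"
}
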