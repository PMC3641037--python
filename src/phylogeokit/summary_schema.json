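{
 "required": {
  "seed": "int",
  "stages": "dict",
  "seeds": "dict",
  "runtime_s": "number"
 },
 "optional": {
  "delta_k_best": "int",
  "gaussian_k": "int",
  "nmds_stress": "number",
  "anosim_global_r": "number",
  "anosim_global_p": "number",
  "ibd_proportion": "number",
  "ibd_pseudo_f": "number",
  "clusters_proportion": "number",
  "barrier_pairs": "int",
  "ldd_pairs": "int",
  "fu_fs": "number",
  "fu_fs_p": "number",
  "mk_p": "number",
  "env_significant_loci": "int",
  "env_threshold": "number",
  "env_n_tests": "int"
 }
}
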