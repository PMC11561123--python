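{
  "_comment": "Levodopa equivalent dose conversion factors (standard published scheme). LED contribution = daily dose (mg) x factor. COMT-inhibitor adjuncts that scale the concurrent levodopa dose are not expressible as per-drug factors and must be pre-applied by the caller. Edit or override freely.",
  "levodopa": 1.0,
  "levodopa_cr": 0.75,
  "duodopa": 1.11,
  "pramipexole": 100.0,
  "ropinirole": 20.0,
  "rotigotine": 30.0,
  "piribedil": 1.0,
  "pergolide": 100.0,
  "cabergoline": 67.0,
  "bromocriptine": 10.0,
  "apomorphine": 10.0,
  "selegiline": 10.0,
  "selegiline_sublingual": 80.0,
  "rasagiline": 100.0,
  "amantadine": 1.0
}
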