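# Measure registry: score ranges, clinical caseness cutoffs and reliable
# change indices, following the NHS Talking Therapies manual conventions.
# These are configuration defaults; services using local variants should
# edit this file and pass it via --registry.
measures:
  PHQ-9:  {min: 0, max: 27,  cutoff: 10, rci: 6}
  GAD-7:  {min: 0, max: 21,  cutoff: 8,  rci: 4}
  WSAS:   {min: 0, max: 40,  cutoff: 10, rci: 8}
  HAI:    {min: 0, max: 54,  cutoff: 18, rci: 4}
  OCI:    {min: 0, max: 168, cutoff: 40, rci: 32}
  PCL-5:  {min: 0, max: 80,  cutoff: 32, rci: 10}
  PDSS:   {min: 0, max: 28,  cutoff: 8,  rci: 5}
  PHQ-15: {min: 0, max: 30,  cutoff: 10, rci: 6}
  SPIN:   {min: 0, max: 68,  cutoff: 19, rci: 10}
adsm: [HAI, OCI, PCL-5, PDSS, PHQ-15, SPIN]
policy:
  caseness_inclusive: true   # score equal to the cutoff counts as a case
  rci_inclusive: true        # change equal to the RCI counts as reliable
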