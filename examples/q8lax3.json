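{
 "sequenceId": "Q8LAx3",
 "sequenceLength": 96,
 "features": [
  {
   "featureId": "UPKB_Q8LAX3_PEPTIDE_74_96",
   "featureStart": 74,
   "featureEnd": 96,
   "typeLabel": "active_peptide",
   "typeCode": "SO:0001064",
   "typeCategory": "Molecule processing",
   "featureLabel": "Elicitor peptide 3",
   "evidenceText": "UniProt",
   "evidenceCode": "",
   "color": "#7DBAA4"
  }
 ]
}
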