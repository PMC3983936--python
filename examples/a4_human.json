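{
 "sequenceId": "a4_human",
 "sequenceLength": 770,
 "features": [
  {
   "featureId": "UNIPROTKB_Q8LAX3_PEPTIDE_54_96",
   "featureStart": 54,
   "featureEnd": 96,
   "typeLabel": "Peptide",
   "typeCode": "SO:0001064",
   "featureLabel": "Elicitor peptide 3",
   "typeCategory": "Molecule processing",
   "evidenceText": "UniProt",
   "evidenceCode": " ",
   "color": "blue"
  },
  {
   "featureId": "UNIPROTKB_Q8LAX3_PEPTIDE_74_96",
   "featureStart": 74,
   "featureEnd": 96,
   "typeLabel": "Active Site",
   "typeCode": "SO:0001064",
   "featureLabel": "Elicitor peptide 3",
   "typeCategory": "Molecule processing",
   "evidenceText": "UniProt",
   "evidenceCode": " ",
   "type": "diamond"
  },
  {
   "featureId": "UPKB_Q8LAX3_DISULFID_75_96",
   "featureStart": 75,
   "featureEnd": 96,
   "typeLabel": "Active Site",
   "typeCode": "SO:0001064",
   "featureLabel": "Elicitor peptide 3",
   "typeCategory": "Molecule processing",
   "evidenceText": "UniProt",
   "evidenceCode": " ",
   "color": "#33FF66",
   "type": "bridge"
  }
 ]
}
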