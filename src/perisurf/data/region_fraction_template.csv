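region,group,fraction_percent
Liver,SMCVP,
Gastrocolic ligament,SMCVP,
Stomach,SMCVP,
Spleen,SMCVP,
Transverse mesocolon: superior layer,SMCVP,
Lesser omentum,SMCVP,
Falciform ligament,SMCVP,
Pancreas,SMCVP,
Gastrosplenic ligament,SMCVP,
Teres ligament,SMCVP,
Duodenum,SMCVP,
Left triangular ligament,SMCVP,
Gall bladder,SMCVP,
Lienorenal ligament,SMCVP,
Right triangular ligament,SMCVP,
Abdominal esophagus,SMCVP,
Right diaphragmatic wall,SMCPP,
Left diaphragmatic wall,SMCPP,
Right antero-lateral supraumbilical wall,SMCPP,
Left antero-lateral supraumbilical wall,SMCPP,
Right dorsal supracolic parietal wall,SMCPP,
Left dorsal supracolic parietal wall,SMCPP,
Mesentery,IMCVP,
Jejunum-ileum,IMCVP,
Greater omentum,IMCVP,
Sigmoid colon,IMCVP,
Transverse colon,IMCVP,
Transverse mesocolon: inferior layer,IMCVP,
Caecum v. appendix ascending colon,IMCVP,
Sigmoid mesocolon,IMCVP,
Uterus and broad ligaments,IMCVP,
Rectum,IMCVP,
Descending colon,IMCVP,
Urinary bladder,IMCVP,
Right antero-lateral infraumbilical wall,IMCPP,
Left antero-lateral infraumbilical wall,IMCPP,
Left dorsal infracolic parietal wall,IMCPP,
Right dorsal infracolic parietal wall,IMCPP,
Left lateral pelvic wall,IMCPP,
Right lateral pelvic wall,IMCPP,
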