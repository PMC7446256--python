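region,group,fraction_percent
Liver,SMCVP,2.5
Gastrocolic ligament,SMCVP,2.5
Stomach,SMCVP,2.5
Spleen,SMCVP,2.5
Transverse mesocolon: superior layer,SMCVP,2.5
Lesser omentum,SMCVP,2.5
Falciform ligament,SMCVP,2.5
Pancreas,SMCVP,2.5
Gastrosplenic ligament,SMCVP,2.5
Teres ligament,SMCVP,2.5
Duodenum,SMCVP,2.5
Left triangular ligament,SMCVP,2.5
Gall bladder,SMCVP,2.5
Lienorenal ligament,SMCVP,2.5
Right triangular ligament,SMCVP,2.5
Abdominal esophagus,SMCVP,2.5
Right diaphragmatic wall,SMCPP,2.5
Left diaphragmatic wall,SMCPP,2.5
Right antero-lateral supraumbilical wall,SMCPP,2.5
Left antero-lateral supraumbilical wall,SMCPP,2.5
Right dorsal supracolic parietal wall,SMCPP,2.5
Left dorsal supracolic parietal wall,SMCPP,2.5
Mesentery,IMCVP,2.5
Jejunum-ileum,IMCVP,2.5
Greater omentum,IMCVP,2.5
Sigmoid colon,IMCVP,2.5
Transverse colon,IMCVP,2.5
Transverse mesocolon: inferior layer,IMCVP,2.5
Caecum v. appendix ascending colon,IMCVP,2.5
Sigmoid mesocolon,IMCVP,2.5
Uterus and broad ligaments,IMCVP,2.5
Rectum,IMCVP,2.5
Descending colon,IMCVP,2.5
Urinary bladder,IMCVP,2.5
Right antero-lateral infraumbilical wall,IMCPP,2.5
Left antero-lateral infraumbilical wall,IMCPP,2.5
Left dorsal infracolic parietal wall,IMCPP,2.5
Right dorsal infracolic parietal wall,IMCPP,2.5
Left lateral pelvic wall,IMCPP,2.5
Right lateral pelvic wall,IMCPP,2.5
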