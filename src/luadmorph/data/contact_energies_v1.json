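{
 "version": 1,
 "comment": "Baseline contact energies (package defaults). Preset deltas are applied on top of these named entries.",
 "J": {
  "cancer.apical|cancer.apical": 16.0,
  "cancer.apical|cancer.basal": 16.0,
  "cancer.apical|cancer.cytosol": 16.0,
  "cancer.apical|cancer.lateral": 16.0,
  "cancer.apical|ecm": 25.0,
  "cancer.apical|growing_stromal": 25.0,
  "cancer.apical|medium": 4.0,
  "cancer.apical|mucus": 4.0,
  "cancer.apical|normal_epithelial.apical": 16.0,
  "cancer.apical|normal_epithelial.basal": 16.0,
  "cancer.apical|normal_epithelial.cytosol": 16.0,
  "cancer.apical|normal_epithelial.lateral": 16.0,
  "cancer.apical|stromal": 25.0,
  "cancer.basal|cancer.basal": 16.0,
  "cancer.basal|cancer.cytosol": 16.0,
  "cancer.basal|cancer.lateral": 16.0,
  "cancer.basal|ecm": 3.0,
  "cancer.basal|growing_stromal": 3.0,
  "cancer.basal|medium": 16.0,
  "cancer.basal|mucus": 16.0,
  "cancer.basal|normal_epithelial.apical": 16.0,
  "cancer.basal|normal_epithelial.basal": 16.0,
  "cancer.basal|normal_epithelial.cytosol": 16.0,
  "cancer.basal|normal_epithelial.lateral": 16.0,
  "cancer.basal|stromal": 3.0,
  "cancer.cytosol|cancer.cytosol": 16.0,
  "cancer.cytosol|cancer.lateral": 16.0,
  "cancer.cytosol|ecm": 25.0,
  "cancer.cytosol|growing_stromal": 25.0,
  "cancer.cytosol|medium": 16.0,
  "cancer.cytosol|mucus": 16.0,
  "cancer.cytosol|normal_epithelial.apical": 16.0,
  "cancer.cytosol|normal_epithelial.basal": 16.0,
  "cancer.cytosol|normal_epithelial.cytosol": 16.0,
  "cancer.cytosol|normal_epithelial.lateral": 16.0,
  "cancer.cytosol|stromal": 25.0,
  "cancer.lateral|cancer.lateral": 2.0,
  "cancer.lateral|ecm": 25.0,
  "cancer.lateral|growing_stromal": 25.0,
  "cancer.lateral|medium": 16.0,
  "cancer.lateral|mucus": 16.0,
  "cancer.lateral|normal_epithelial.apical": 16.0,
  "cancer.lateral|normal_epithelial.basal": 16.0,
  "cancer.lateral|normal_epithelial.cytosol": 16.0,
  "cancer.lateral|normal_epithelial.lateral": 2.0,
  "cancer.lateral|stromal": 25.0,
  "ecm|ecm": 5.0,
  "ecm|growing_stromal": 5.0,
  "ecm|medium": 16.0,
  "ecm|mucus": 16.0,
  "ecm|normal_epithelial.apical": 25.0,
  "ecm|normal_epithelial.basal": 3.0,
  "ecm|normal_epithelial.cytosol": 25.0,
  "ecm|normal_epithelial.lateral": 25.0,
  "ecm|stromal": 5.0,
  "growing_stromal|growing_stromal": 5.0,
  "growing_stromal|medium": 16.0,
  "growing_stromal|mucus": 16.0,
  "growing_stromal|normal_epithelial.apical": 25.0,
  "growing_stromal|normal_epithelial.basal": 3.0,
  "growing_stromal|normal_epithelial.cytosol": 25.0,
  "growing_stromal|normal_epithelial.lateral": 25.0,
  "growing_stromal|stromal": 5.0,
  "medium|medium": 16.0,
  "medium|mucus": 8.0,
  "medium|normal_epithelial.apical": 4.0,
  "medium|normal_epithelial.basal": 16.0,
  "medium|normal_epithelial.cytosol": 16.0,
  "medium|normal_epithelial.lateral": 16.0,
  "medium|stromal": 16.0,
  "mucus|mucus": 4.0,
  "mucus|normal_epithelial.apical": 4.0,
  "mucus|normal_epithelial.basal": 16.0,
  "mucus|normal_epithelial.cytosol": 16.0,
  "mucus|normal_epithelial.lateral": 16.0,
  "mucus|stromal": 16.0,
  "normal_epithelial.apical|normal_epithelial.apical": 16.0,
  "normal_epithelial.apical|normal_epithelial.basal": 16.0,
  "normal_epithelial.apical|normal_epithelial.cytosol": 16.0,
  "normal_epithelial.apical|normal_epithelial.lateral": 16.0,
  "normal_epithelial.apical|stromal": 25.0,
  "normal_epithelial.basal|normal_epithelial.basal": 16.0,
  "normal_epithelial.basal|normal_epithelial.cytosol": 16.0,
  "normal_epithelial.basal|normal_epithelial.lateral": 16.0,
  "normal_epithelial.basal|stromal": 3.0,
  "normal_epithelial.cytosol|normal_epithelial.cytosol": 16.0,
  "normal_epithelial.cytosol|normal_epithelial.lateral": 16.0,
  "normal_epithelial.cytosol|stromal": 25.0,
  "normal_epithelial.lateral|normal_epithelial.lateral": 2.0,
  "normal_epithelial.lateral|stromal": 25.0,
  "stromal|stromal": 5.0
 },
 "J_internal": {
  "cancer.apical|cancer.apical": 1.0,
  "cancer.apical|cancer.basal": 1.0,
  "cancer.apical|cancer.cytosol": 1.0,
  "cancer.apical|cancer.lateral": 1.0,
  "cancer.basal|cancer.basal": 1.0,
  "cancer.basal|cancer.cytosol": 1.0,
  "cancer.basal|cancer.lateral": 1.0,
  "cancer.cytosol|cancer.cytosol": 1.0,
  "cancer.cytosol|cancer.lateral": 1.0,
  "cancer.lateral|cancer.lateral": 1.0,
  "normal_epithelial.apical|normal_epithelial.apical": 1.0,
  "normal_epithelial.apical|normal_epithelial.basal": 1.0,
  "normal_epithelial.apical|normal_epithelial.cytosol": 1.0,
  "normal_epithelial.apical|normal_epithelial.lateral": 1.0,
  "normal_epithelial.basal|normal_epithelial.basal": 1.0,
  "normal_epithelial.basal|normal_epithelial.cytosol": 1.0,
  "normal_epithelial.basal|normal_epithelial.lateral": 1.0,
  "normal_epithelial.cytosol|normal_epithelial.cytosol": 1.0,
  "normal_epithelial.cytosol|normal_epithelial.lateral": 1.0,
  "normal_epithelial.lateral|normal_epithelial.lateral": 1.0
 }
}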