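# Partial, hand-assembled working vocabulary of ovary- and uterus-related
# MedDRA Preferred Terms, each assigned to one of the ten fixed categories.
# This is NOT the complete ~383-PT vocabulary used for a full screen; supply a
# complete two-column (pt,category) file for production use.
pt,category
Ovarian adenoma,ovarian cysts and neoplasms
Ovarian cancer stage I,ovarian cysts and neoplasms
Ovarian germ cell teratoma benign,ovarian cysts and neoplasms
Ovarian cyst,ovarian cysts and neoplasms
Ovarian cyst ruptured,ovarian cysts and neoplasms
Haemorrhagic ovarian cyst,ovarian cysts and neoplasms
Ovarian neoplasm,ovarian cysts and neoplasms
Ovarian cancer,ovarian cysts and neoplasms
Ovarian epithelial cancer,ovarian cysts and neoplasms
Uterine polyp,uterine neoplasms
Uterine leiomyoma,uterine neoplasms
Endometrial cancer,uterine neoplasms
Uterine cancer,uterine neoplasms
Uterine neoplasm,uterine neoplasms
Endometrial adenocarcinoma,uterine neoplasms
Cervix carcinoma,cervix neoplasms
Adenocarcinoma of the cervix,cervix neoplasms
Cervix carcinoma stage III,cervix neoplasms
Cervical polyp,cervix neoplasms
Cervix neoplasm,cervix neoplasms
Ovarian failure,ovarian disorders (excl cysts and neoplasms)
Premature ovarian failure,ovarian disorders (excl cysts and neoplasms)
Ovarian haemorrhage,ovarian disorders (excl cysts and neoplasms)
Ovarian torsion,ovarian disorders (excl cysts and neoplasms)
Oophoritis,ovarian disorders (excl cysts and neoplasms)
Ovarian disorder,ovarian disorders (excl cysts and neoplasms)
Endometrial hyperplasia,uterine disorders (excl neoplasms)
Endometrial disorder,uterine disorders (excl neoplasms)
Adenomyosis,uterine disorders (excl neoplasms)
Endometriosis,uterine disorders (excl neoplasms)
Uterine prolapse,uterine disorders (excl neoplasms)
Endometrial hypertrophy,uterine disorders (excl neoplasms)
Uterine mass,uterine disorders (excl neoplasms)
Endometrial atrophy,uterine disorders (excl neoplasms)
Uterine disorder,uterine disorders (excl neoplasms)
Cervix disorder,cervix disorders (excl neoplasms)
Cervical incompetence,cervix disorders (excl neoplasms)
Cervical dysplasia,cervix disorders (excl neoplasms)
Cervicitis,cervix disorders (excl neoplasms)
Cervical erosion,cervix disorders (excl neoplasms)
Androgenetic alopecia,endocrine disorders of gonadal function
Polycystic ovaries,endocrine disorders of gonadal function
Precocious puberty,endocrine disorders of gonadal function
Blood testosterone increased,endocrine disorders of gonadal function
Hirsutism,endocrine disorders of gonadal function
Blood oestrogen decreased,endocrine disorders of gonadal function
Anovulatory cycle,endocrine disorders of gonadal function
Dysfunctional uterine bleeding,menstrual cycle and uterine bleeding disorders
Uterine haemorrhage,menstrual cycle and uterine bleeding disorders
Menstruation irregular,menstrual cycle and uterine bleeding disorders
Menorrhagia,menstrual cycle and uterine bleeding disorders
Amenorrhoea,menstrual cycle and uterine bleeding disorders
Oligomenorrhoea,menstrual cycle and uterine bleeding disorders
Polymenorrhoea,menstrual cycle and uterine bleeding disorders
Dysmenorrhoea,menstrual cycle and uterine bleeding disorders
Metrorrhagia,menstrual cycle and uterine bleeding disorders
Menometrorrhagia,menstrual cycle and uterine bleeding disorders
Menopausal symptoms,menopause related conditions
Postmenopausal haemorrhage,menopause related conditions
Premature menopause,menopause related conditions
Menopausal disorder,menopause related conditions
Postmenopausal symptoms,menopause related conditions
Dyspareunia,sexual function disorders
Sexual dysfunction,sexual function disorders
Disturbance in sexual arousal,sexual function disorders
Orgasm abnormal,sexual function disorders
Anorgasmia,sexual function disorders
Libido increased,sexual function disorders
Libido decreased,sexual function disorders
Female sexual arousal disorder,sexual function disorders
Vaginismus,sexual function disorders
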