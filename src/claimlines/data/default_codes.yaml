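# Default drug-class and ICD-10 rule sets for claims-based mBC treatment-pattern
# analysis.  Drug classes carry both substance names and ATC codes so that event
# streams may use either vocabulary.  Edit a copy of this file and pass it to
# `load_code_rules` to change any classification without touching code.
version: "2026.09"

drug_classes:
  CDK46I:
    - palbociclib
    - ribociclib
    - abemaciclib
    - L01EF01
    - L01EF02
    - L01EF03
  AI:
    - letrozole
    - anastrozole
    - exemestane
    - L02BG04
    - L02BG03
    - L02BG06
  FULVESTRANT:
    - fulvestrant
    - L02BA03
  TAMOXIFEN:
    - tamoxifen
    - L02BA01
  EVEROLIMUS:
    - everolimus
    - L01EG02
    - L04AA18
  HER2_TARGETED:
    - trastuzumab
    - pertuzumab
    - lapatinib
    - neratinib
    - afatinib
    - ado-trastuzumab emtansine
    - trastuzumab emtansine
    - L01FD01
    - L01FD02
    - L01FD03
    - L01EH01
    - L01EH02
    - L01EB03
  CHEMO:
    - chemotherapy
    - capecitabine
    - paclitaxel
    - docetaxel
    - eribulin
    - vinorelbine
    - cyclophosphamide
    - gemcitabine
    - carboplatin
    - L01BC06
    - L01CD01
    - L01CD02
    - L01XX41
    - L01CA04
    - L01AA01
    - L01BC05
    - L01XA02
  OTHER_ANTICANCER:
    - alpelisib
    - olaparib
    - L01EM03
    - L01XK01

# Any unmapped ATC code under these prefixes falls back to CHEMO (cytotoxics
# are reported as a single class; agent identity is never used downstream).
chemo_atc_prefixes:
  - L01

secondary_malignancy:
  prefixes: [C77, C78, C79]
  exclusions: [C773, C792]

# Secondary-site codes counted as visceral disease:
# liver C78.7, lung C78.0, pleura C78.2, peritoneum C78.6,
# adrenal C79.7, ovary C79.6, brain C79.3
visceral_codes: [C780, C782, C786, C787, C793, C796, C797]

# Charlson comorbidity conditions, Quan-2005 ICD-10 code lists with the
# original Charlson weights.  The two malignancy categories (any malignancy,
# metastatic solid tumour) are intentionally absent: in a cancer cohort the
# index disease is not a comorbidity.
charlson:
  - condition: myocardial_infarction
    weight: 1
    codes: [I21, I22, I252]
  - condition: congestive_heart_failure
    weight: 1
    codes: [I099, I110, I130, I132, I255, I420, I425, I426, I427, I428, I429,
            I43, I50, P290]
  - condition: peripheral_vascular_disease
    weight: 1
    codes: [I70, I71, I731, I738, I739, I771, I790, I792, K551, K558, K559,
            Z958, Z959]
  - condition: cerebrovascular_disease
    weight: 1
    codes: [G45, G46, H340, I60, I61, I62, I63, I64, I65, I66, I67, I68, I69]
  - condition: dementia
    weight: 1
    codes: [F00, F01, F02, F03, F051, G30, G311]
  - condition: chronic_pulmonary_disease
    weight: 1
    codes: [I278, I279, J40, J41, J42, J43, J44, J45, J46, J47, J60, J61,
            J62, J63, J64, J65, J66, J67, J684, J701, J703]
  - condition: rheumatic_disease
    weight: 1
    codes: [M05, M06, M315, M32, M33, M34, M351, M353, M360]
  - condition: peptic_ulcer_disease
    weight: 1
    codes: [K25, K26, K27, K28]
  - condition: mild_liver_disease
    weight: 1
    codes: [B18, K700, K701, K702, K703, K709, K713, K714, K715, K717,
            K73, K74, K760, K762, K763, K764, K768, K769, Z944]
  - condition: diabetes_uncomplicated
    weight: 1
    codes: [E100, E101, E106, E108, E109, E110, E111, E116, E118, E119,
            E120, E121, E126, E128, E129, E130, E131, E136, E138, E139,
            E140, E141, E146, E148, E149]
  - condition: diabetes_complicated
    weight: 2
    codes: [E102, E103, E104, E105, E107, E112, E113, E114, E115, E117,
            E122, E123, E124, E125, E127, E132, E133, E134, E135, E137,
            E142, E143, E144, E145, E147]
  - condition: hemiplegia_paraplegia
    weight: 2
    codes: [G041, G114, G801, G802, G81, G82, G830, G831, G832, G833,
            G834, G839]
  - condition: renal_disease
    weight: 2
    codes: [I120, I131, N032, N033, N034, N035, N036, N037, N052, N053,
            N054, N055, N056, N057, N18, N19, N250, Z490, Z491, Z492,
            Z940, Z992]
  - condition: moderate_severe_liver_disease
    weight: 3
    codes: [I850, I859, I864, I982, K704, K711, K721, K729, K765, K766, K767]
  - condition: aids_hiv
    weight: 6
    codes: [B20, B21, B22, B24]

# Within each pair the first (more severe) condition supersedes the second:
# a patient coded for both contributes only the severe weight.
charlson_hierarchy:
  - [diabetes_complicated, diabetes_uncomplicated]
  - [moderate_severe_liver_disease, mild_liver_disease]
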