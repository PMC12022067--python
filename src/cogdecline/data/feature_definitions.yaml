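# Versioned battery of baseline cutoff features (22 predictors).
# Comparators are strict: gt 2 means "score of 3 or more" on a 0-4 item
# (moderate or severe); lt cutoffs read "lower/less than".  Ordinal
# "equals-or-exceeds" thresholds are stored as gt on (threshold - 1).
version: 1
features:
  - name: upsit_low
    source: upsit_total
    description: UPSIT score lower than 31 for females or 30 for males
    comparator: lt
    sex_specific_cutoffs: {female: 31, male: 30}
    hypothesis_sign: -1
    hypothesis_group: olfaction
  - name: lightheadedness_moderate
    source: updrs1_12
    description: Moderate or severe light-headedness on standing (MDS-UPDRS 1.12)
    comparator: gt
    cutoff: 2
    hypothesis_sign: 1
    hypothesis_group: hypoperfusion
  - name: speech_disorder_moderate
    source: updrs2_1
    description: Moderate or severe speech disorder (MDS-UPDRS 2.1)
    comparator: gt
    cutoff: 2
    hypothesis_sign: 1
    hypothesis_group: bulbar
  - name: chewing_swallowing_moderate
    source: updrs2_3
    description: Moderate or severe chewing and swallowing difficulty (MDS-UPDRS 2.3)
    comparator: gt
    cutoff: 2
    hypothesis_sign: 1
    hypothesis_group: bulbar
  - name: tremor_moderate
    source: updrs2_10
    description: Moderate or severe tremor (MDS-UPDRS 2.10)
    comparator: gt
    cutoff: 2
    hypothesis_sign: 1
    hypothesis_group: tremor
  - name: right_rigidity_high
    source: right_rigidity
    description: Sum of right upper and lower limb MDS-UPDRS III rigidity higher than 5
    comparator: gt
    cutoff: 5
    hypothesis_sign: 1
    hypothesis_group: rigidity
  - name: stroke_history
    source: stroke
    description: History of ischemic or hemorrhagic stroke
    comparator: flag
    hypothesis_sign: 1
    hypothesis_group: cerebrovascular
  - name: stool_incontinence
    source: scopa_7
    description: Involuntary loss of stools in the past month (SCOPA-AUT 7)
    comparator: gt
    cutoff: 0
    hypothesis_sign: 1
    hypothesis_group: bowel
  - name: urinary_frequency
    source: scopa_12
    description: Passing urine again within 2 hours in the past month (SCOPA-AUT 12)
    comparator: gt
    cutoff: 0
    hypothesis_sign: 1
    hypothesis_group: urinary
  - name: nocturia
    source: scopa_13
    description: Passing urine at night in the past month (SCOPA-AUT 13)
    comparator: gt
    cutoff: 0
    hypothesis_sign: 1
    hypothesis_group: urinary
  - name: fainting
    source: scopa_16
    description: Fainting in the past 6 months (SCOPA-AUT 16)
    comparator: gt
    cutoff: 0
    hypothesis_sign: 1
    hypothesis_group: hypoperfusion
  - name: scopa_total_high
    source: scopa_total
    description: SCOPA-AUT total score higher than 20
    comparator: gt
    cutoff: 20
    hypothesis_sign: 1
    hypothesis_group: autonomic_total
  - name: feeling_upset
    source: stai_x1_6
    description: I feel upset, very much so (STAI-X1 question 6)
    comparator: gt
    cutoff: 3
    hypothesis_sign: 1
    hypothesis_group: anxiety
  - name: difficulties_piling_up
    source: stai_x2_8
    description: Difficulties are piling up so that I cannot overcome them, almost always (STAI-X2 question 8)
    comparator: gt
    cutoff: 3
    hypothesis_sign: 1
    hypothesis_group: anxiety
  - name: taking_things_hard
    source: stai_x2_11
    description: I am inclined to take things hard, almost always (STAI-X2 question 11)
    comparator: gt
    cutoff: 3
    hypothesis_sign: 1
    hypothesis_group: anxiety
  - name: persistent_rumination
    source: stai_x2_18
    description: I take disappointments so keenly that I cannot get them out of my mind, almost always (STAI-X2 question 18)
    comparator: gt
    cutoff: 3
    hypothesis_sign: 1
    hypothesis_group: anxiety
  - name: trait_anxiety_high
    source: stai_x2_total
    description: Trait anxiety (STAI-X2) total score higher than 50
    comparator: gt
    cutoff: 50
    hypothesis_sign: 1
    hypothesis_group: anxiety
  - name: rhino_naming_fail
    source: moca_naming_rhino
    description: Unable to name the rhinoceros picture (MoCA naming)
    comparator: lt
    cutoff: 1
    hypothesis_sign: -1
    hypothesis_group: cognition
  - name: clock_numbers_fail
    source: moca_clock_numbers
    description: Clock numbers drawn incorrectly (MoCA clock drawing)
    comparator: lt
    cutoff: 1
    hypothesis_sign: -1
    hypothesis_group: cognition
  - name: visuospatial_executive_low
    source: moca_visuospatial_executive
    description: MoCA visuospatial/executive domain total less than 3
    comparator: lt
    cutoff: 3
    hypothesis_sign: -1
    hypothesis_group: cognition
  - name: moca_zscore_low
    source: moca_zscore
    description: Normalized total MoCA z-score lower than -1
    comparator: lt
    cutoff: -1
    hypothesis_sign: -1
    hypothesis_group: cognition
  - name: dream_vocalization
    source: rbdsq_6_1
    description: Speaking, shouting, swearing or laughing loudly during dreams (RBDSQ 6.1)
    comparator: flag
    hypothesis_sign: 1
    hypothesis_group: rbd
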