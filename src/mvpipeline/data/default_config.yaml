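# Default synthetic-cohort parameterization.
#
# Anchors: a 143-patient mitral valve surgical series (86 repairs / 57
# replacements) with etiology counts 55 prolapse / 24 endocarditis /
# 39 rheumatic / 16 atrial MR / 4 Barlow / 5 other, published
# stratum-conditional lesion frequencies (e.g. P2 prolapse in 74.5% of
# prolapse etiology; restriction in 77.3% of the complex stratum, driven
# by rheumatic disease; calcification absent from the simple stratum;
# atrial MR confined to the simple stratum), a stratum-wise replacement
# gradient of 13.2% / 26.2% / 79.5%, and a score-vs-approach concordance
# (AUC) of 0.75.  Per-etiology frequencies below are the free knobs that
# reproduce those stratum-conditional marginals at large n.

etiology_mix:
  mitral_valve_prolapse: 0.3846      # 55/143
  infective_endocarditis: 0.1678     # 24/143
  rheumatic_heart_disease: 0.2727    # 39/143
  atrial_mitral_regurgitation: 0.1119  # 16/143
  barlows_syndrome: 0.0280           # 4/143
  other: 0.0350                      # 5/143

# Log-odds of replacement = a + b*score + c*restriction + d*calc_leaflet
# + e*(perforation/cleft present).  The direct lesion terms encode the
# three high-risk lesions that push surgeons toward replacement beyond the
# summed score (restriction foremost); their relative sizes follow that
# importance ordering, and (a, b) are grid-searched so large cohorts hit
# the score-vs-approach concordance 0.75, the replacement fraction
# 57/143 = 0.399, and a Bayes accuracy advantage of the full lesion model
# over the best score-only cutoff of roughly ten accuracy points.
outcome_link: [-1.90, 0.06, 2.2, 1.2, 1.0]

# Unsuccessful-repair rates per stratum: 4/33, 6/45, 5/9 in the anchor series.
adverse_rate_by_stratum:
  simple: 0.121
  intermediate: 0.133
  complex: 0.556

male_fraction: 0.615   # 88/143 male
age_mean: 52.0
age_sd: 13.0

feature_freqs:
  # Degenerative prolapse: posterior leaflet dominant (P2 in ~3/4),
  # excessive motion, frequent ruptured chords, no calcification/fusion.
  mitral_valve_prolapse:
    prolapse:
      prolapse_p1: 0.18
      prolapse_p2: 0.78
      prolapse_p3: 0.40
      prolapse_a1: 0.12
      prolapse_a2: 0.30
      prolapse_a3: 0.25
      prolapse_anterolateral_commissure: 0.0
      prolapse_posteromedial_commissure: 0.18
    ruptured_chordae: 0.60
    morphology: [0.42, 0.53, 0.05]   # normal, thickening, redundant
    calc_leaflet: 0.02
    calc_annulus: 0.0
    calc_chordae: 0.03
    commissure_fusion: 0.0
    vegetation: [0.98, 0.02, 0.0]
    perforation_cleft: [0.92, 0.07, 0.01]
    motion: [0.06, 0.92, 0.02]       # normal, excessive, restriction
  # Endocarditis: vegetations and perforations dominate; little prolapse.
  infective_endocarditis:
    prolapse:
      prolapse_p1: 0.04
      prolapse_p2: 0.20
      prolapse_p3: 0.08
      prolapse_a1: 0.10
      prolapse_a2: 0.20
      prolapse_a3: 0.12
      prolapse_anterolateral_commissure: 0.0
      prolapse_posteromedial_commissure: 0.04
    ruptured_chordae: 0.30
    morphology: [0.30, 0.62, 0.08]
    calc_leaflet: 0.10
    calc_annulus: 0.0
    calc_chordae: 0.08
    commissure_fusion: 0.02
    vegetation: [0.15, 0.50, 0.35]
    perforation_cleft: [0.40, 0.38, 0.22]
    motion: [0.25, 0.63, 0.12]
  # Rheumatic disease: thickened leaflets, restriction, commissural fusion
  # and leaflet/chordal calcification; annular calcification not observed.
  rheumatic_heart_disease:
    prolapse:
      prolapse_p1: 0.03
      prolapse_p2: 0.05
      prolapse_p3: 0.05
      prolapse_a1: 0.05
      prolapse_a2: 0.05
      prolapse_a3: 0.08
      prolapse_anterolateral_commissure: 0.0
      prolapse_posteromedial_commissure: 0.05
    ruptured_chordae: 0.15
    morphology: [0.02, 0.92, 0.06]
    calc_leaflet: 0.82
    calc_annulus: 0.0
    calc_chordae: 0.90
    commissure_fusion: 0.90
    vegetation: [0.97, 0.03, 0.0]
    perforation_cleft: [0.95, 0.03, 0.02]
    motion: [0.01, 0.07, 0.92]
  # Annular-dilatation (atrial) regurgitation: structurally near-normal valve.
  atrial_mitral_regurgitation:
    prolapse:
      prolapse_p1: 0.0
      prolapse_p2: 0.0
      prolapse_p3: 0.0
      prolapse_a1: 0.0
      prolapse_a2: 0.0
      prolapse_a3: 0.0
      prolapse_anterolateral_commissure: 0.0
      prolapse_posteromedial_commissure: 0.0
    ruptured_chordae: 0.0
    morphology: [0.92, 0.08, 0.0]
    calc_leaflet: 0.0
    calc_annulus: 0.0
    calc_chordae: 0.0
    commissure_fusion: 0.0
    vegetation: [1.0, 0.0, 0.0]
    perforation_cleft: [0.98, 0.02, 0.0]
    motion: [0.78, 0.22, 0.0]
  # Barlow: diffuse redundant billowing tissue, multisegment prolapse.
  barlows_syndrome:
    prolapse:
      prolapse_p1: 0.60
      prolapse_p2: 0.80
      prolapse_p3: 0.60
      prolapse_a1: 0.35
      prolapse_a2: 0.60
      prolapse_a3: 0.40
      prolapse_anterolateral_commissure: 0.0
      prolapse_posteromedial_commissure: 0.40
    ruptured_chordae: 0.40
    morphology: [0.05, 0.10, 0.85]
    calc_leaflet: 0.05
    calc_annulus: 0.0
    calc_chordae: 0.05
    commissure_fusion: 0.0
    vegetation: [1.0, 0.0, 0.0]
    perforation_cleft: [0.95, 0.05, 0.0]
    motion: [0.05, 0.90, 0.05]
  # Other regurgitation/stenosis: mild mixed pathology.
  other:
    prolapse:
      prolapse_p1: 0.05
      prolapse_p2: 0.15
      prolapse_p3: 0.08
      prolapse_a1: 0.05
      prolapse_a2: 0.08
      prolapse_a3: 0.05
      prolapse_anterolateral_commissure: 0.0
      prolapse_posteromedial_commissure: 0.03
    ruptured_chordae: 0.10
    morphology: [0.60, 0.38, 0.02]
    calc_leaflet: 0.08
    calc_annulus: 0.02
    calc_chordae: 0.08
    commissure_fusion: 0.05
    vegetation: [0.97, 0.03, 0.0]
    perforation_cleft: [0.90, 0.08, 0.02]
    motion: [0.50, 0.40, 0.10]
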