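# Proton assignment table for triglyceride 1H spectra in CDCl3.
#
# Standard functional-group assignments for acylglycerol chains; the
# three discriminating resonances are the omega-3 terminal methyl
# triplet at 0.977 ppm, the non-omega-3 terminal methyl triplet at
# 0.881 ppm and the bis-allylic methylene signal at 2.78 ppm.
# "multiplet" lineshapes are rendered as a 5-line binomial pattern.
linewidth_hz: 1.2

groups:
  methyl_omega3:     {center_ppm: 0.977, multiplicity: triplet,  j_hz: 7.5}
  methyl_other:      {center_ppm: 0.881, multiplicity: triplet,  j_hz: 6.9}
  bulk_methylene:    {center_ppm: 1.290, multiplicity: multiplet, j_hz: 6.5}
  beta_methylene:    {center_ppm: 1.610, multiplicity: multiplet, j_hz: 7.0}
  allylic:           {center_ppm: 2.020, multiplicity: multiplet, j_hz: 6.8}
  alpha_carbonyl:    {center_ppm: 2.300, multiplicity: triplet,  j_hz: 7.5}
  bis_allylic:       {center_ppm: 2.780, multiplicity: triplet,  j_hz: 6.5}
  glycerol_sn13:     {center_ppm: 4.220, multiplicity: multiplet, j_hz: 5.9}
  glycerol_sn2:      {center_ppm: 5.260, multiplicity: multiplet, j_hz: 5.0}
  olefinic:          {center_ppm: 5.350, multiplicity: multiplet, j_hz: 6.0}

# Protons per acyl chain contributed to each group.  Glycerol backbone
# protons (4 sn-1/3 + 1 sn-2 per triglyceride) are booked per chain,
# i.e. divided by three.
protons:
  palmitic:   # 16:0
    methyl_other: 3
    bulk_methylene: 24
    beta_methylene: 2
    alpha_carbonyl: 2
    glycerol_sn13: 1.3333333333333333
    glycerol_sn2: 0.3333333333333333
  stearic:    # 18:0
    methyl_other: 3
    bulk_methylene: 28
    beta_methylene: 2
    alpha_carbonyl: 2
    glycerol_sn13: 1.3333333333333333
    glycerol_sn2: 0.3333333333333333
  oleic:      # 18:1 n-9
    methyl_other: 3
    bulk_methylene: 20
    beta_methylene: 2
    allylic: 4
    alpha_carbonyl: 2
    olefinic: 2
    glycerol_sn13: 1.3333333333333333
    glycerol_sn2: 0.3333333333333333
  linoleic:   # 18:2 n-6
    methyl_other: 3
    bulk_methylene: 14
    beta_methylene: 2
    allylic: 4
    alpha_carbonyl: 2
    bis_allylic: 2
    olefinic: 4
    glycerol_sn13: 1.3333333333333333
    glycerol_sn2: 0.3333333333333333
  linolenic:  # 18:3 n-3 (the omega-3 chain)
    methyl_omega3: 3
    bulk_methylene: 8
    beta_methylene: 2
    allylic: 4
    alpha_carbonyl: 2
    bis_allylic: 4
    olefinic: 6
    glycerol_sn13: 1.3333333333333333
    glycerol_sn2: 0.3333333333333333

# Composition-independent lines: residual protonated solvent and the
# TMS reference.  Amplitudes are in the same per-chain proton-weight
# units as the groups above; both fall inside default blinded regions.
extra_lines:
  - {label: residual_chcl3, center_ppm: 7.26, amplitude: 0.02,
     multiplicity: singlet, j_hz: 0.0}
  - {label: tms, center_ppm: 0.0, amplitude: 0.05,
     multiplicity: singlet, j_hz: 0.0}
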