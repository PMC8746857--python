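# Built-in fatty-acid compositions (molar fractions of acyl chains).
#
# Representative literature-style values for retail oils; each entry sums
# to 1.  These are editable defaults, not measurements: downstream tests
# rely only on qualitative contrasts (e.g. hempseed >> olive in
# alpha-linolenic, high-oleic seed oils close to olive in oleic), never
# on the exact numbers.
oils:
  olive:
    oleic: 0.723
    palmitic: 0.130
    linoleic: 0.100
    stearic: 0.040
    linolenic: 0.007
  high_oleic_canola:
    oleic: 0.740
    linoleic: 0.140
    linolenic: 0.030
    palmitic: 0.060
    stearic: 0.030
  hazelnut:
    oleic: 0.789
    linoleic: 0.120
    palmitic: 0.060
    stearic: 0.030
    linolenic: 0.001
  peanut:
    oleic: 0.537
    linoleic: 0.300
    palmitic: 0.120
    stearic: 0.040
    linolenic: 0.003
  high_oleic_safflower:
    oleic: 0.7785
    linoleic: 0.140
    palmitic: 0.060
    stearic: 0.020
    linolenic: 0.0015
  high_oleic_sunflower:
    oleic: 0.818
    linoleic: 0.100
    palmitic: 0.045
    stearic: 0.035
    linolenic: 0.002
  grapeseed:
    linoleic: 0.700
    oleic: 0.186
    palmitic: 0.070
    stearic: 0.040
    linolenic: 0.004
  hempseed:
    linoleic: 0.560
    linolenic: 0.190
    oleic: 0.150
    palmitic: 0.070
    stearic: 0.030
  soybean:
    linoleic: 0.530
    oleic: 0.250
    palmitic: 0.110
    stearic: 0.040
    linolenic: 0.070
  cottonseed:
    linoleic: 0.540
    palmitic: 0.260
    oleic: 0.173
    stearic: 0.025
    linolenic: 0.002
  almond:
    oleic: 0.689
    linoleic: 0.230
    palmitic: 0.065
    stearic: 0.015
    linolenic: 0.001
  argan:
    oleic: 0.479
    linoleic: 0.330
    palmitic: 0.130
    stearic: 0.060
    linolenic: 0.001

# Relative standard deviations of multiplicative bottle-to-bottle /
# cultivar jitter applied when sampling a panel of nominally identical
# oils.  The authentic olive reference class is modelled as a curated
# panel: broad spread in linoleate (the dominant cultivar axis) but a
# tightly regulated omega-3 (alpha-linolenic) content, which is what
# makes normalisation to the omega-3 methyl signal produce the tight
# reference cluster the screen relies on.
cultivar_rel_sd:
  oleic: 0.020
  palmitic: 0.050
  stearic: 0.060
  linoleic: 0.150
  linolenic: 0.008
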