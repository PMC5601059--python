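# Default synthetic-cohort parameters: a two-group (adult / elderly)
# gut-microbiome study design with 14 family-level taxa.
#
# Per-group Dirichlet concentrations are mean composition x total
# concentration (200). The elderly composition lowers Bifidobacteriaceae
# and raises Clostridiaceae, Clostridiales;f__ and Enterobacteriaceae;
# Lachnospiraceae absorbs the compensating mass so every other taxon has
# an identical marginal distribution in both groups. Desulfovibrionaceae
# sits below the 0.1% median-abundance filter in both groups.
#
# Coating probabilities differ between groups only for Clostridiaceae
# (0.55 vs 0.30) and Enterobacteriaceae (0.60 vs 0.20), modelling a
# decreased taxon-specific IgA response in the elderly.

n_per_group: 20
read_depth: 46000
depth_mode: multinomial
total_concentration: 200.0

taxa:
  - Bacteroidaceae
  - Bifidobacteriaceae
  - Clostridiaceae
  - "Clostridiales;f__"
  - Coriobacteriaceae
  - Desulfovibrionaceae
  - Enterobacteriaceae
  - Erysipelotrichaceae
  - Lachnospiraceae
  - Porphyromonadaceae
  - Prevotellaceae
  - Rikenellaceae
  - Ruminococcaceae
  - Streptococcaceae

mean_composition:
  adult:
    Bacteroidaceae: 0.140
    Bifidobacteriaceae: 0.080
    Clostridiaceae: 0.008
    "Clostridiales;f__": 0.020
    Coriobacteriaceae: 0.020
    Desulfovibrionaceae: 0.0006
    Enterobacteriaceae: 0.005
    Erysipelotrichaceae: 0.015
    Lachnospiraceae: 0.360
    Porphyromonadaceae: 0.035
    Prevotellaceae: 0.0514
    Rikenellaceae: 0.020
    Ruminococcaceae: 0.220
    Streptococcaceae: 0.025
  elderly:
    Bacteroidaceae: 0.140
    Bifidobacteriaceae: 0.020
    Clostridiaceae: 0.030
    "Clostridiales;f__": 0.050
    Coriobacteriaceae: 0.020
    Desulfovibrionaceae: 0.0006
    Enterobacteriaceae: 0.030
    Erysipelotrichaceae: 0.015
    Lachnospiraceae: 0.343
    Porphyromonadaceae: 0.035
    Prevotellaceae: 0.0514
    Rikenellaceae: 0.020
    Ruminococcaceae: 0.220
    Streptococcaceae: 0.025

coating_prob:
  adult:
    Bacteroidaceae: 0.40
    Bifidobacteriaceae: 0.45
    Clostridiaceae: 0.55
    "Clostridiales;f__": 0.55
    Coriobacteriaceae: 0.30
    Desulfovibrionaceae: 0.30
    Enterobacteriaceae: 0.60
    Erysipelotrichaceae: 0.30
    Lachnospiraceae: 0.30
    Porphyromonadaceae: 0.35
    Prevotellaceae: 0.30
    Rikenellaceae: 0.25
    Ruminococcaceae: 0.25
    Streptococcaceae: 0.20
  elderly:
    Bacteroidaceae: 0.40
    Bifidobacteriaceae: 0.45
    Clostridiaceae: 0.30
    "Clostridiales;f__": 0.55
    Coriobacteriaceae: 0.30
    Desulfovibrionaceae: 0.30
    Enterobacteriaceae: 0.20
    Erysipelotrichaceae: 0.30
    Lachnospiraceae: 0.30
    Porphyromonadaceae: 0.35
    Prevotellaceae: 0.30
    Rikenellaceae: 0.25
    Ruminococcaceae: 0.25
    Streptococcaceae: 0.20

# fecal IgA concentration (ug/ml): log-normal, identical in both groups
fecal_iga_log_mean: 6.2
fecal_iga_log_sd: 0.4
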