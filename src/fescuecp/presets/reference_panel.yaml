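# Study-panel preset: 12 Festuca accessions in six groups, a 20,056-column
# chloroplast amplicon alignment with 167 planted polymorphic loci
# (129 substitutions, 25 single-base deletions, 13 multi-base indels of
# 3-47 bp). Each entry plants `count` loci whose derived state is fixed in
# the `split` groups and absent elsewhere. The split weights are the
# L1-closest integer system to the reported pairwise polymorphism counts
# under the 167-locus total (the reported counts violate cut-metric
# constraints and admit no exact split realisation); the four headline pairs
# (pratensis-Mediterranean 117, glaucescens-Rhizomatous 2,
# Continental-Mediterranean 103, pratensis-Continental 42) are exact.
# Exactly four multi-base indels (47, 32, 8, 3 bp: the documented NFTCHL
# product-size differences) separate the Mediterranean and Continental
# morphotypes.
name: reference_panel
alignment_length: 20056
seed: 466687
indel_length_range: [3, 47]
group_of:
  Ensign: F_pratensis
  Rita: F_pratensis
  PI283312: F_mairei
  PI283313: F_mairei
  PI289651: F_glaucescens
  PI289654: F_glaucescens
  Torpedo: Rhizomatous
  Prosper: Mediterranean
  Resolute: Mediterranean
  FlechaMaxQ: Mediterranean
  TexomaMaxQII: Continental
  KY31: Continental
loci:
  - {class: snp, split: [F_glaucescens], count: 1}
  - {class: del1, split: [Rhizomatous], count: 1}
  - {class: snp, split: [F_mairei], count: 22}
  - {class: del1, split: [F_mairei], count: 6}
  - {class: indel_multi, split: [F_mairei], length: 4}
  - {class: indel_multi, split: [F_mairei], length: 5}
  - {class: indel_multi, split: [F_mairei], length: 6}
  - {class: indel_multi, split: [F_mairei], length: 9}
  - {class: snp, split: [Mediterranean], count: 28}
  - {class: del1, split: [Mediterranean], count: 6}
  - {class: snp, split: [F_pratensis], count: 18}
  - {class: del1, split: [F_pratensis], count: 6}
  - {class: indel_multi, split: [F_pratensis], length: 4}
  - {class: indel_multi, split: [F_pratensis], length: 5}
  - {class: indel_multi, split: [F_pratensis], length: 7}
  - {class: indel_multi, split: [F_pratensis], length: 10}
  - {class: del1, split: [F_glaucescens, Rhizomatous], count: 1}
  - {class: indel_multi, split: [F_glaucescens, Rhizomatous], length: 6}
  - {class: snp, split: [F_mairei, Mediterranean], count: 45}
  - {class: del1, split: [F_mairei, Mediterranean], count: 5}
  - {class: indel_multi, split: [F_mairei, Mediterranean], length: 47}
  - {class: indel_multi, split: [F_mairei, Mediterranean], length: 32}
  - {class: indel_multi, split: [F_mairei, Mediterranean], length: 8}
  - {class: indel_multi, split: [F_mairei, Mediterranean], length: 3}
  - {class: snp, split: [F_mairei, F_pratensis, Mediterranean], count: 13}
  - {class: snp, split: [F_glaucescens, F_mairei, Mediterranean, Rhizomatous], count: 1}
  - {class: snp, split: [F_glaucescens, F_mairei, F_pratensis, Mediterranean, Rhizomatous], count: 1}
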