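{
  "description": "Candidate lncRNA sets taken forward experimentally in the original colorectal-cancer screen whose published list columns ship in crc_lncrna_lists.tsv. The full B-and-C intersection additionally contains LINC00312, which the original screen did not take forward; the fixture runner flags such members rather than dropping them.",
  "tumor_suppressor": ["DLEU1", "LINC00261", "LINC00483", "LINC01207", "MCF2L-AS1"],
  "oncogene": ["MEG3", "RUNX1-IT1", "TP73-AS1"],
  "bait_up": ["CYP1B1", "NPR3", "RGL2", "SLIT2", "TSPAN2"],
  "bait_down": ["ACOT7", "AGPAT5", "ATP5B", "AURKAIP1", "CASP1", "CEP55", "CXCL3", "FUT4", "GSR", "HNRNPAB", "IDO1", "KIF11", "MCM5", "PBK", "PIGR", "RANBP1", "SCO2", "TOE1", "TTLL12"],
  "excluded_mirnas_no_targets": ["miR-4464", "miR-4660", "miR-4743-3p", "miR-7978"]
}
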