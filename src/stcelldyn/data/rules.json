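{
  "neurotransmitter": {
    "Glutamatergic": [["Slc17a6", "Slc17a7", "Slc17a8"]],
    "GABAergic": [["Slc32a1", "Slc18a2"], ["Gad1", "Gad2", "Aldh1a1"]],
    "Glycinergic": [["Slc6a5"]],
    "Cholinergic": [["Slc18a3"], ["Chat"]],
    "Dopaminergic": [["Slc6a3", "Slc18a2"], ["Th"], ["Ddc"]],
    "Serotonergic": [["Slc6a4", "Slc18a2"], ["Tph2"], ["Ddc"]],
    "Noradrenergic": [["Slc6a2", "Slc18a2"], ["Dbh"]],
    "Histaminergic": [["Slc18a2"], ["Hdc"]]
  },
  "glial": {
    "Astrocytes": [["Gfap", "Aldoc", "S100b"], ["Slc1a3", "Aqp4", "Agt"]],
    "Microglia": [["Cx3cr1", "Csf1r", "Itgam"], ["Iba1", "C1qc", "Tmem119", "P2ry12"]],
    "Oligodendrocytes": [["Plp1", "Mbp", "Mobp", "Mag"], ["Olig1", "Olig2", "Sox10", "Nkx2-2"]],
    "Ependymal": [["Foxj1"], ["Ttr", "Aqp1"]],
    "Endothelial": [["Cldn5", "Pecam1", "Vwf"], ["Flt1", "Kdr"]]
  }
}
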