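{
  "total_residues": 276,
  "secondary_structure": {
    "coil": ["A:1-1", "A:5-11", "A:29-29", "A:44-56", "A:78-121", "A:125-152",
             "A:162-177", "A:184-190", "A:199-200", "A:204-210", "A:231-259",
             "A:265-269", "A:273-276"],
    "helix": ["A:12-28", "A:30-43", "A:57-77", "A:122-124", "A:153-161",
              "A:178-183", "A:191-198", "A:201-203", "A:211-230", "A:260-264"],
    "turn": ["A:2-4", "A:269-272"]
  },
  "rmsd_shift_regions": ["A:2-6", "A:238-245", "A:265-275"],
  "rmsf_increase_regions": ["A:90-96", "A:131-137", "A:173-177"],
  "low_contact_regions": ["A:44-49", "A:201-208"],
  "low_contact_regions_selected": ["A:44-49"],
  "exclusions": {
    "glycine": [[53, "adjacent to the active site"]],
    "alanine_scan": [[38, "copper-binding histidine"],
                     [191, "copper-binding histidine"],
                     [195, "copper-binding histidine"],
                     [216, "copper-binding histidine"],
                     [217, "copper-binding histidine"]],
    "low_contact": [[201, "substrate pocket"], [202, "substrate pocket"],
                    [203, "substrate pocket"], [204, "substrate pocket"],
                    [205, "substrate pocket"], [206, "substrate pocket"],
                    [207, "substrate pocket"], [208, "substrate pocket"]]
  }
}
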