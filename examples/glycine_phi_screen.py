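"""Glycine rigidification screen on the packaged tyrosinase phi table.

A glycine with backbone phi < 0 sits in right-handed backbone territory
and can usually be replaced by a bulkier residue to rigidify a flexible
loop; one with phi > 0 cannot without distorting the backbone.
"""

import thermoscreen as ts
from thermoscreen import data

table = data.glycine_phi_table()
print(f"glycines in the table:            {len(table)}")

negatives = ts.glycine_phi_candidates(table)
print(f"glycines with phi < 0:            {len(negatives)}  -> {negatives}")

# G53 sits next to the catalytic centre; mutating it risks activity,
# so it is excluded by hand (the screen has no active-site detector).
kept = ts.glycine_phi_candidates(table, exclusions=[53])
print(f"after active-site exclusion (53): {len(kept)}  -> {kept}")

print("\nThese sites are candidate positions for glycine-to-bulky "
      "substitutions; each still needs an energy screen to pick the "
      "substitution.")
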