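"""The packaged ARC-111 analogue activity table.

Loads the 34-compound activity fixture (22 experimental analogues
assayed against RPMI8402 tumor cells, 12 theoretical designs), shows
the train/test partition, and demonstrates the micromolar IC50 ->
pIC50 conversion.
"""

import svrqsar as q

table = q.load_arc111_fixture()
expt = table.frame[table.frame["split"] != "theoretical"]

print(f"experimental compounds: {len(expt)}")
print(f"pIC50 range: {expt['pIC50'].min():.3f} .. {expt['pIC50'].max():.3f}")
print(f"training set: {len(table.train_ids)} compounds")
print(f"test set:     {len(table.test_ids)} compounds -> {table.test_ids}")
print(f"theoretical designs (reference predictions only): "
      f"{len(table.ids('theoretical'))}")

# pIC50 is the negative log10 of the molar IC50: 1 uM -> 6, 1 nM -> 9.
for ic50_um in (1.0, 0.1, 0.003):
    print(f"IC50 {ic50_um:6.3f} uM  ->  pIC50 {q.ic50_to_pic50(ic50_um):.3f}")
# The fixture's most potent analogue (compound 9, pIC50 9.523) therefore
# inhibits at roughly 0.3 nM.
print(f"compound 9: pIC50 {table.frame.loc['9', 'pIC50']} "
      f"= IC50 {q.pic50_to_ic50(table.frame.loc['9', 'pIC50']) * 1e3:.2f} nM")
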