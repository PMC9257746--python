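"""Build pair descriptors from molecular structures.

Derives molecular weight and Lipinski donor/acceptor counts from SMILES
for furosemide and the bislactam coformer bisVCap, estimates a Hansen
hydrogen-bonding parameter for furosemide with the group-contribution
surrogate, and assembles a feature vector for the pair.
"""

from coamscreen import (
    PairRecord,
    Role,
    assemble_feature_vector,
    derive_component_from_structure,
    estimate_hansen_dh,
)
import dataclasses

api = derive_component_from_structure(
    "NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl", "furosemide", Role.API
)
cof = derive_component_from_structure(
    "CC(N1CCCCCC1=O)/C=C/N2CCCCCC2=O", "bisVCap", Role.COFORMER
)
for rec in (api, cof):
    print(f"{rec.name}: MW={rec.mw:.2f} g/mol, HBD={rec.hbd}, HBA={rec.hba}")

# Hoftyzer-Van Krevelen surrogate for δh (the pair difference is what
# the model uses; solver-derived values are preferred when available).
dh_api = estimate_hansen_dh(
    {"carboxylic_acid": 1, "secondary_amine": 1, "primary_amine": 1,
     "ether": 1, "sulfone": 1, "chloride": 1},
    molar_volume=205.0,
)
dh_cof = estimate_hansen_dh({"amide": 2}, molar_volume=270.0)
print(f"surrogate δh: furosemide {dh_api:.2f}, bisVCap {dh_cof:.2f} MPa^0.5")

api = dataclasses.replace(api, delta_h_hansen=dh_api, mu=-9.5)
cof = dataclasses.replace(cof, delta_h_hansen=dh_cof, mu=-6.0)
pair = PairRecord(api=api, coformer=cof, dh_mix=-1.1, dh_hb=-0.9)
fv = assemble_feature_vector(api, cof, pair)
print("feature vector:")
for name in ("avg_mw", "sum_hbd_minus_hba", "dh_mix", "dh_hb", "d_delta_h", "d_mu"):
    print(f"  {name:18s} {getattr(fv, name):8.3f}")

# avg_mw and the donor/acceptor sum describe the pair's size and
# hydrogen-bonding balance; the enthalpies and the δh/μ differences
# capture how energetically favourable mixing is.
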