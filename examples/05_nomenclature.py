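"""Unified SRO nomenclature from phylogenetic group assignments.

Names follow four rules: previously named A. thaliana proteins keep their
names; every other family member is <species abbreviation>SRO<number>;
the number is 1 for group I and 2 for group II; and letter suffixes a, b,
c... separate multiple members of one group in discovery order.
"""

from srokit import domain_arch as da

def call(rid, group):
    return da.ArchitectureCall(record_id=rid, domains=[],
                               structural_type="A", group=group)

# three poplar group-I proteins, two group-II
poplar = [call(f"POPTR_{i}", "I") for i in range(3)] + \
         [call(f"POPTR_{i}", "II") for i in range(3, 5)]
print("poplar:", da.assign_names("Pt", poplar))

# a single grapevine member per group gets no suffix
vitis = [call("GSVIVT_1", "I"), call("GSVIVT_2", "II")]
print("grapevine:", da.assign_names("Vv", vitis))

# A. thaliana records in the registry keep their established names
at = [call("At1g32230", None), call("At5g62520", None)]
registry = {"At1g32230": "AtRCD1", "At5g62520": "AtSRO5"}
print("thale cress:", da.assign_names("At", at, existing=registry))
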