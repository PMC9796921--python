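"""Classify observed inner-barcode combinations into chimera types.

Uses a minimal three-group design (group 1: pairs Aa,Bb,Cc,Dd; group 2:
Aa,Bb; group 3: Cc,Dd) and walks through one example of each class.
"""

from quadchim import build_three_group_scheme, classify_combination

scheme = build_three_group_scheme()

examples = [
    ("mg1", "A", "a", "the fixed pair Aa is used in group 1"),
    ("mg1", "A", "b", "both tags used in group 1, but never paired"),
    ("mg2", "B", "c", "B is used in group 2, c only elsewhere"),
    ("mg2", "C", "d", "neither tag in group 2; Cd is no fixed pair"),
    ("mg2", "D", "d", "neither tag in group 2, but Dd is genuine elsewhere"),
]

for group_id, i5, i7, why in examples:
    cls = classify_combination(i5, i7, scheme.group(group_id), scheme)
    print(f"{i5}{i7} in {group_id}: {cls.value:8s} ({why})")

print()
print(
    "A type-IV call is the dangerous one: in a group using every fixed "
    "pair the same molecule would have been counted as a genuine sample."
)
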