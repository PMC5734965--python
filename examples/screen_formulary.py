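"""Screen a candidate proprietary name against a small formulary.

Run:  python examples/screen_formulary.py
"""

from lasamatch import canonicalize, classify, match_value

candidate = "LOPRAX"
formulary = ["LOPROX", "TOPAMAX", "AXAR", "KEFLEX", "LETROX", "NAFTIN"]

cand = canonicalize(candidate)
ranked = sorted(
    (
        (entry, match_value(cand, canonicalize(entry)).percent)
        for entry in formulary
    ),
    key=lambda r: (-r[1], r[0]),
)

print(f"candidate: {candidate}")
for entry, percent in ranked:
    print(f"  {percent:5.1f}%  {classify(percent):<7} {entry}")
# LOPROX tops the list: five of six letters align at the same displacement.
# A registrar would reject or re-review any candidate with a high-band hit.
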