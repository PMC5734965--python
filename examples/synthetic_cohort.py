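"""Generate a synthetic cohort and verify the score ordering it predicts.

Run:  python examples/synthetic_cohort.py
"""

import numpy as np

from lasamatch import (
    CanonicalName,
    CohortSpec,
    EditSpec,
    MatchParams,
    generate_cohort,
    match_value,
)

spec = CohortSpec(
    n_pairs=300,
    edit_grid=[
        EditSpec(),                            # identical
        EditSpec(n_adjacent_transpositions=1), # one adjacent swap
        EditSpec(n_substitutions=1),           # one substitution
        EditSpec(n_substitutions=2),           # two substitutions
    ],
    length_distribution={8: 1.0},
    seed=7,
    unique_letters=True,
)
cohort = generate_cohort(spec)

params = MatchParams(end_markers=False)
for label, mask in [
    ("identical", cohort.n_substitutions.eq(0) & cohort.n_adjacent_transpositions.eq(0)),
    ("1 transposition", cohort.n_adjacent_transpositions.eq(1)),
    ("1 substitution", cohort.n_substitutions.eq(1)),
    ("2 substitutions", cohort.n_substitutions.eq(2)),
]:
    rows = cohort[mask]
    vals = [
        match_value(CanonicalName.from_text(r.base),
                    CanonicalName.from_text(r.variant), params).value
        for r in rows.itertuples()
    ]
    print(f"{label:>16}: mean match {np.mean(vals):.4f} over {len(vals)} pairs")
# Expected ordering 1.0 > 0.9291 > 0.875 > 0.75: a transposed pair keeps both
# letters' evidence (at displacements +-1) while each substitution removes a
# letter's evidence entirely -- the leniency that motivates spatial coding.
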