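"""Build the bundled synthetic cathepsin-B-like specificity matrix.

The real cathepsin-B subsite-preference table is a database export that is
not redistributable here, so the package bundles a synthetic stand-in.  It
is constructed as the smallest L1 perturbation of a biologically motivated
prior (dibasic preference at P1/P2, mild Gly/Ala/Ser tolerance at P1',
mild Leu/Phe preference at P2) subject to linear constraints requiring that,
for each of the four study constructs, the three bonds matching the
published proteolytic fragment table outscore every other interior bond by
a fixed margin.  Scores are in arbitrary additive units.

Run from the repository root:

    python scripts/build_cleavage_fixture.py

Writes src/nanovax/data/cathepsin_b_synthetic.tsv (deterministic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from nanovax.cleavage import SUBSITES, SpecificityMatrix, write_matrix
from nanovax.constructs import AMINO_ACIDS, STUDY_SEQUENCES

# Published single-cut bond sets for the four study constructs.
CUT_SETS = {
    "p1": {5, 9, 15},
    "p2": {9, 15, 17},
    "p3": {5, 8, 18},
    "p4": {5, 18, 20},
}

MARGIN = 0.5  # score gap between selected and unselected bonds
N_CELLS = 8 * 20


def prior_matrix() -> np.ndarray:
    """Cathepsin-B-like prior, arbitrary additive units."""
    prior = np.zeros((8, 20))
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    row = {s: i for i, s in enumerate(SUBSITES)}
    for res, val in (("K", 2.0), ("R", 2.0), ("L", 1.0), ("F", 1.0)):
        prior[row["P2"], idx[res]] = val
    for res, val in (("K", 2.0), ("R", 2.0)):
        prior[row["P1"], idx[res]] = val
    for res, val in (("G", 1.0), ("A", 0.5), ("S", 0.5)):
        prior[row["P1'"], idx[res]] = val
    return prior


def window_counts(seq: str, bond: int) -> np.ndarray:
    """Indicator vector over the 160 matrix cells for the window at *bond*."""
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    v = np.zeros((8, 20))
    for subsite_i, off in enumerate((-3, -2, -1, 0, 1, 2, 3, 4)):
        res = seq[bond + off - 1]
        v[subsite_i, idx[res]] += 1.0
    return v.ravel()


def build() -> SpecificityMatrix:
    prior = prior_matrix().ravel()

    # inequalities: for each peptide, score(selected) - score(other) >= MARGIN
    rows = []
    for pid, seq in STUDY_SEQUENCES.items():
        L = len(seq)
        bonds = range(4, L - 3)
        selected = CUT_SETS[pid]
        for a in selected:
            wa = window_counts(seq, a)
            for b in bonds:
                if b in selected:
                    continue
                rows.append(window_counts(seq, b) - wa)  # <= -MARGIN
    A_scores = np.array(rows)
    n_ineq = A_scores.shape[0]

    # variables: [S (160), u (160)]; minimize sum(u) s.t. |S - prior| <= u
    c = np.concatenate([np.zeros(N_CELLS), np.ones(N_CELLS)])
    A_ub = np.vstack(
        [
            np.hstack([A_scores, np.zeros((n_ineq, N_CELLS))]),
            np.hstack([np.eye(N_CELLS), -np.eye(N_CELLS)]),
            np.hstack([-np.eye(N_CELLS), -np.eye(N_CELLS)]),
        ]
    )
    b_ub = np.concatenate([-MARGIN * np.ones(n_ineq), prior, -prior])
    bounds = [(-10.0, 10.0)] * N_CELLS + [(0.0, None)] * N_CELLS
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LP infeasible: {res.message}")

    scores = np.round(res.x[:N_CELLS], 2).reshape(8, 20) + 0.0
    scores[scores == 0.0] = 0.0  # normalize -0.0
    df = pd.DataFrame(scores, index=list(SUBSITES), columns=list(AMINO_ACIDS))
    return SpecificityMatrix(
        protease="cathepsin B",
        scores=df,
        provenance=(
            "Synthetic cathepsin-B-like subsite preference matrix (not a "
            "database export). L1-minimal perturbation of a dibasic P1/P2, "
            "Gly-tolerant-P1' prior under the constraint that the top-3 "
            "bonds of the four study constructs match their published "
            "fragment sets (margin 0.5). Arbitrary additive score units."
        ),
    )


def verify(matrix: SpecificityMatrix) -> None:
    from nanovax.cleavage import score_windows, select_top_sites

    for pid, seq in STUDY_SEQUENCES.items():
        sites = score_windows(seq, matrix)
        top = {s.bond for s in select_top_sites(sites, 3)}
        assert top == CUT_SETS[pid], f"{pid}: got {sorted(top)}, want {sorted(CUT_SETS[pid])}"
    print("verified: top-3 bonds match the published cut sets for p1-p4")


if __name__ == "__main__":
    matrix = build()
    verify(matrix)
    out = "src/nanovax/data/cathepsin_b_synthetic.tsv"
    write_matrix(matrix, out)
    print(f"wrote {out}")
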