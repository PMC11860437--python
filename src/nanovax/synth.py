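"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its configuration (which carries the
seed): repeated calls produce identical output, and different generators
derive independent random streams from the same seed.  Alongside every
dataset the generating truth (planted regions, planted cut bond, true curve
parameters) is returned so that tests never reverse-engineer it.

What is emulated: the modular construct grammar (anchor + spacer + epitope-
like core + optional CPP tail), a subsite matrix with a planted dibasic
K/R preference at P1/P2, 4PL viability plates with additive Gaussian noise,
and per-locus allele-frequency tables drawn from a Dirichlet.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .assay import DoseResponse, four_pl
from .cleavage import SUBSITES, SpecificityMatrix
from .constructs import AMINO_ACIDS, PeptideConstruct, Region
from .coverage import AlleleFrequencyTable

# stream offsets so generators sharing a seed are mutually independent
_STREAM = {"peptides": 1, "matrix": 2, "plate": 3, "alleles": 4}


@dataclass(frozen=True)
class FourPLTruth:
    lower: float
    upper: float
    ic50: float
    hill: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for all generators.

    Dose grid and replicate count mirror the viability assay layout (five
    replicates; doses bracketing the observed IC50s on a log grid in pM);
    the 4PL truth defaults to the small-particle nanoconjugate estimate.
    Noise is additive Gaussian with SD expressed in response units (per cent
    viability), so 2.0 means 2% of the 0-100 scale.
    """

    seed: int = 0
    # peptide grammar
    anchor: str = "CALNN"
    spacers: tuple[str, ...] = ("KK", "GPGPG")
    cpp: str = "RKKRQRRR"
    core_length_range: tuple[int, int] = (9, 15)
    spacer_prob: float = 0.7
    cpp_prob: float = 0.5
    # specificity matrix
    matrix_background_mean: float = 0.0
    matrix_background_sd: float = 1.0
    dibasic_bonus: float = 8.0
    # dose-response plate
    dose_grid_pM: tuple[float, ...] = (10.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0, 30000.0, 100000.0)
    n_replicates: int = 5
    fourpl_truth: FourPLTruth = FourPLTruth(lower=5.0, upper=100.0, ic50=3308.0, hill=1.0)
    noise_sd: float = 2.0
    # allele frequencies
    loci: tuple[str, ...] = ("DRB1", "DQB1")
    alleles_per_locus: int = 10
    dirichlet_concentration: float = 1.0
    typed_fraction: float = 0.95

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAM[stream], self.seed])

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def make_peptides(cfg: GeneratorConfig, n: int) -> list[PeptideConstruct]:
    """Random constructs with planted anchor/spacer/core/CPP regions.

    The planted regions are attached to each construct as ground truth for
    annotation tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = cfg.rng("peptides")
    lo, hi = cfg.core_length_range
    out = []
    for i in range(n):
        parts: list[tuple[str, str]] = [(cfg.anchor, "anchor")]
        if rng.random() < cfg.spacer_prob:
            parts.append((cfg.spacers[rng.integers(len(cfg.spacers))], "spacer"))
        core_len = int(rng.integers(lo, hi + 1))
        core = "".join(rng.choice(list(AMINO_ACIDS), size=core_len))
        parts.append((core, "epitope"))
        if rng.random() < cfg.cpp_prob:
            parts.append((cfg.cpp, "cpp"))
        seq, regions, pos = "", [], 0
        for motif, kind in parts:
            regions.append(Region(kind=kind, start=pos + 1, end=pos + len(motif), motif=motif))
            seq += motif
            pos += len(motif)
        out.append(PeptideConstruct(id=f"syn{i+1}", sequence=seq, regions=regions))
    return out


def make_matrix(cfg: GeneratorConfig) -> SpecificityMatrix:
    """Background-noise matrix with a planted dibasic K/R bonus at P1 and P2.

    With the bonus much larger than the background SD, the bond whose P2 and
    P1 residues are both basic (for a KK pair at i, i+1 that is the bond
    after the second lysine) outranks every other bond with probability
    approaching 1.
    """
    rng = cfg.rng("matrix")
    scores = rng.normal(
        cfg.matrix_background_mean, cfg.matrix_background_sd, size=(8, 20)
    )
    df = pd.DataFrame(scores, index=list(SUBSITES), columns=list(AMINO_ACIDS))
    for subsite in ("P2", "P1"):
        for res in ("K", "R"):
            df.at[subsite, res] += cfg.dibasic_bonus
    return SpecificityMatrix(
        protease="synthetic dibasic protease",
        scores=df,
        provenance=(
            f"synthetic: Normal({cfg.matrix_background_mean}, "
            f"{cfg.matrix_background_sd}) background + {cfg.dibasic_bonus} "
            "bonus for K/R at P1 and P2; seed "
            f"{cfg.seed}"
        ),
    )


def planted_cut_bond(construct: PeptideConstruct) -> int | None:
    """Ground-truth scissile bond for a construct with a single interior KK.

    Under the planted matrix the preferred cut is after the second residue
    of the dibasic pair (P2 = first K, P1 = second K), i.e. bond i+1 for a
    KK at positions i, i+1.  None when no fully windowable KK bond exists.
    """
    seq = construct.sequence
    L = len(seq)
    for i in range(1, L):  # i is 1-based position of first K
        if seq[i - 1 : i + 1] == "KK":
            bond = i + 1
            if 4 <= bond <= L - 4:
                return bond
    return None


def make_dose_response(cfg: GeneratorConfig) -> tuple[DoseResponse, FourPLTruth]:
    """4PL plate: truth curve plus additive Gaussian noise per replicate."""
    if len(cfg.dose_grid_pM) < 4:
        raise ValueError("dose grid must contain >= 4 doses")
    rng = cfg.rng("plate")
    doses = np.asarray(cfg.dose_grid_pM, dtype=float)
    t = cfg.fourpl_truth
    clean = four_pl(doses, t.lower, t.upper, t.ic50, t.hill)
    responses = clean[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(len(doses), cfg.n_replicates)
    ) if cfg.noise_sd > 0 else np.repeat(clean[:, None], cfg.n_replicates, axis=1)
    return DoseResponse(doses=doses, responses=responses, control_mean=t.upper), t


def make_allele_table(cfg: GeneratorConfig) -> AlleleFrequencyTable:
    """Per-locus Dirichlet frequencies scaled to sum to the typed fraction."""
    if not cfg.loci:
        raise ValueError("need >= 1 locus")
    rng = cfg.rng("alleles")
    rows = []
    for locus in cfg.loci:
        freqs = rng.dirichlet(
            [cfg.dirichlet_concentration] * cfg.alleles_per_locus
        ) * cfg.typed_fraction
        for j, f in enumerate(freqs, start=1):
            rows.append({"locus": locus, "allele": f"{locus}*{j:02d}", "frequency": float(f)})
    return AlleleFrequencyTable(
        frequencies=pd.DataFrame(rows), population="synthetic"
    )
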