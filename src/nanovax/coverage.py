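"""Theoretical MHC population coverage from allele frequencies.

Given a table of MHC allele frequencies for a target population and the set
of alleles predicted to present an epitope, the fraction of individuals
carrying at least one presenting allele is computed under Hardy-Weinberg
diploidy: with covered allele-frequency mass p at a locus, the phenotypic
coverage is 1 - (1 - p)^2, and loci combine under independence as
1 - prod_l (1 - p_l)^2.  Allele-frequency shortfall at a locus (untyped
alleles, per-locus sums below 1) is treated as uncovered mass unless
renormalization is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

_SUM_TOL = 1e-9


class MissingAlleleError(KeyError):
    """A covered allele is absent from the frequency table."""


@dataclass
class AlleleFrequencyTable:
    """Rows of (locus, allele, frequency) for one population."""

    frequencies: pd.DataFrame
    population: str = ""

    def __post_init__(self) -> None:
        df = self.frequencies.copy()
        required = {"locus", "allele", "frequency"}
        if not required.issubset(df.columns):
            raise ValueError(f"frequency table needs columns {sorted(required)}")
        df["frequency"] = df["frequency"].astype(float)
        if (df["frequency"] < 0).any():
            raise ValueError("negative allele frequency")
        sums = df.groupby("locus")["frequency"].sum()
        bad = sums[sums > 1 + _SUM_TOL]
        if not bad.empty:
            raise ValueError(
                f"allele frequencies at locus {bad.index[0]!r} sum to "
                f"{bad.iloc[0]:.6f} > 1"
            )
        if df.duplicated(subset=["locus", "allele"]).any():
            dup = df[df.duplicated(subset=["locus", "allele"])].iloc[0]
            raise ValueError(f"duplicate allele {dup['allele']!r} at locus {dup['locus']!r}")
        self.frequencies = df.reset_index(drop=True)

    @property
    def loci(self) -> list[str]:
        return sorted(self.frequencies["locus"].unique())

    def locus_frequencies(self, locus: str) -> pd.Series:
        sub = self.frequencies[self.frequencies["locus"] == locus]
        if sub.empty:
            raise KeyError(f"locus {locus!r} not in table")
        return sub.set_index("allele")["frequency"]


@dataclass
class BindingSet:
    """Alleles predicted to present an epitope."""

    epitope: str
    covered: set[tuple[str, str]] = field(default_factory=set)

    def alleles_at(self, locus: str) -> set[str]:
        return {allele for loc, allele in self.covered if loc == locus}


def locus_coverage(
    table: AlleleFrequencyTable,
    binding: BindingSet,
    locus: str,
    renormalize: bool = False,
) -> float:
    """Phenotypic coverage 1 - (1 - p)^2 at one locus.

    p is the summed frequency of covered alleles; with ``renormalize`` the
    locus frequencies are first scaled to sum to 1.
    """
    freqs = table.locus_frequencies(locus)
    covered = binding.alleles_at(locus)
    missing = covered - set(freqs.index)
    if missing:
        raise MissingAlleleError(
            f"covered allele {sorted(missing)[0]!r} absent from locus {locus!r}"
        )
    p = float(freqs.loc[sorted(covered)].sum()) if covered else 0.0
    if renormalize and freqs.sum() > 0:
        p /= float(freqs.sum())
    p = min(p, 1.0)
    return 1.0 - (1.0 - p) ** 2


def combined_coverage(
    table: AlleleFrequencyTable, binding: BindingSet, renormalize: bool = False
) -> float:
    """Multi-locus coverage 1 - prod_l (1 - p_l)^2 assuming independence."""
    loci = table.loci
    if not loci:
        raise ValueError("frequency table has no loci")
    for loc, _ in binding.covered:
        if loc not in loci:
            raise MissingAlleleError(f"locus {loc!r} of binding set absent from table")
    miss_prob = 1.0
    for locus in loci:
        cov = locus_coverage(table, binding, locus, renormalize=renormalize)
        miss_prob *= 1.0 - cov
    return 1.0 - miss_prob


# ---------------------------------------------------------------------------
# TSV I/O

def read_frequency_table(path: str | Path) -> AlleleFrequencyTable:
    """TSV columns: population, locus, allele, frequency."""
    df = pd.read_csv(path, sep="\t", comment="#")
    population = ""
    if "population" in df.columns:
        pops = df["population"].unique()
        population = str(pops[0]) if len(pops) else ""
        df = df.drop(columns=["population"])
    return AlleleFrequencyTable(frequencies=df, population=population)


def write_frequency_table(table: AlleleFrequencyTable, path: str | Path) -> None:
    df = table.frequencies.copy()
    df.insert(0, "population", table.population or "synthetic")
    df.to_csv(path, sep="\t", index=False)


def read_binding_set(path: str | Path, epitope: str = "") -> BindingSet:
    """TSV columns: locus, allele."""
    df = pd.read_csv(path, sep="\t", comment="#")
    covered = {(str(r.locus), str(r.allele)) for r in df.itertuples()}
    return BindingSet(epitope=epitope, covered=covered)
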