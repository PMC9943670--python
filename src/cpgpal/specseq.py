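"""Spec-seq: degenerate-library enrichment and relative binding energies.

Specificity-by-sequencing exposes a degenerate probe library (e.g. ATNNNNAT,
256 variants) to a protein, gel-separates the monomer- and dimer-bound bands,
and sequences each band together with the input pool. The fractional
enrichment of a variant in a bound band, relative to its input share, is
proportional to its Boltzmann occupancy, so relative binding energies follow
as ``ddG_i = -ln(E_i / E_ref)`` in kT units (lower = tighter binding; the
reference sequence sits at 0 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "LibraryTemplate",
    "CountTable",
    "EnergyTable",
    "enumerate_library",
    "fractional_enrichment",
    "relative_energy",
    "rank_dimer_preference",
    "compare_conditions",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class LibraryTemplate:
    """A degenerate pattern over {A,C,G,T,N} and its concrete variants."""

    pattern: str
    variants: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class CountTable:
    """Per-variant sequencing counts for the input pool and bound bands."""

    counts: pd.DataFrame  # index: sequence; columns: input, monomer, dimer
    condition: str = "unmethylated"

    def __post_init__(self) -> None:
        required = {"input"}
        if not required <= set(self.counts.columns):
            raise ValueError("count table needs at least an 'input' column")
        if (self.counts < 0).any().any():
            raise ValueError("counts must be non-negative")

    def band(self, name: str) -> pd.Series:
        if name not in self.counts.columns:
            raise ValueError(f"band {name!r} not present (have {list(self.counts.columns)})")
        return self.counts[name]


@dataclass(frozen=True)
class EnergyTable:
    """Relative binding energies (kT) with ddG(reference) = 0."""

    energies: pd.Series  # index: sequence, values: kT
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.energies.index:
            raise ValueError(f"reference {self.reference!r} not in the library")
        if not np.isfinite(self.energies.to_numpy()).all():
            raise ValueError("energies must be finite")


def enumerate_library(pattern: str) -> LibraryTemplate:
    """Expand every N in ``pattern`` over A/C/G/T, lexicographic order.

    "ATNNNNAT" yields the 256 octamer variants of the monomer-site library;
    "ATGNNNAT" the 64 variants of its half-fixed derivative.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    bad = set(pattern) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in pattern: {sorted(bad)}")
    slots = [(_BASES if c == "N" else c) for c in pattern]
    variants = tuple("".join(p) for p in product(*slots))
    return LibraryTemplate(pattern=pattern, variants=variants)


def fractional_enrichment(
    counts: CountTable, band: str = "dimer", pseudocount: float = 0.5
) -> pd.Series:
    """Bound-band share over input share, per variant.

    ``E_i = ((b_i + a) / sum(b + a)) / ((n_i + a) / sum(n + a))`` with ``a``
    the pseudocount. With ``a > 0`` every enrichment is strictly positive;
    with ``a = 0`` a zero input count raises.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    b = counts.band(band).astype(float) + pseudocount
    n = counts.band("input").astype(float) + pseudocount
    if counts.band("input").sum() <= 0:
        raise ValueError("input band has zero total count")
    if pseudocount == 0 and (n == 0).any():
        raise ValueError("zero input counts require pseudocount > 0")
    enrichment = (b / b.sum()) / (n / n.sum())
    enrichment.name = f"enrichment_{band}"
    return enrichment


def relative_energy(enrichment: pd.Series, reference_sequence: str) -> EnergyTable:
    """Convert enrichments to relative binding energies in kT.

    ``ddG_i = -ln(E_i / E_ref)``; the reference is pinned at 0 and any other
    reference choice only shifts all energies by a constant.
    """
    if reference_sequence not in enrichment.index:
        raise ValueError(f"reference {reference_sequence!r} not in the library")
    e_ref = float(enrichment.loc[reference_sequence])
    if e_ref <= 0 or (enrichment <= 0).any():
        raise ValueError("non-positive enrichment; use a pseudocount > 0")
    energies = -np.log(enrichment / e_ref)
    energies.name = "ddG_kT"
    return EnergyTable(energies=energies, reference=reference_sequence)


def rank_dimer_preference(enrichment: pd.Series) -> pd.Series:
    """Variants sorted by decreasing dimer-band enrichment.

    Ties break lexicographically on the sequence so the ranking is
    deterministic; the first index is the preferred dimer site.
    """
    df = enrichment.rename("E").rename_axis("sequence").reset_index()
    df = df.sort_values(["E", "sequence"], ascending=[False, True], kind="mergesort")
    return df.set_index("sequence")["E"]


def compare_conditions(
    table_meth: EnergyTable, table_unmeth: EnergyTable, top_k: int | None = None
) -> tuple[pd.Series, float]:
    """Methylated-minus-unmethylated energy differences and rank concordance.

    Returns per-variant ``dddG = ddG_meth - ddG_unmeth`` and the Spearman
    correlation of the two energy scales over the ``top_k`` tightest binders
    (union of the top k under either condition; all variants if None). A
    correlation near 1 with small |dddG| means methylation leaves the
    specificity landscape intact.
    """
    idx_m, idx_u = table_meth.energies.index, table_unmeth.energies.index
    if set(idx_m) != set(idx_u):
        raise ValueError("energy tables cover different libraries")
    meth = table_meth.energies
    unmeth = table_unmeth.energies.reindex(idx_m)
    dddg = (meth - unmeth).rename("dddG_kT")

    if top_k is None:
        chosen = list(idx_m)
    else:
        top_m = meth.nsmallest(top_k).index
        top_u = unmeth.nsmallest(top_k).index
        chosen = sorted(set(top_m) | set(top_u))
    rho = spearmanr(meth.loc[chosen], unmeth.loc[chosen]).statistic
    return dddg, float(rho)
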