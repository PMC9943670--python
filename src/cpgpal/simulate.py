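"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one experimental input of the study design — a
genome with planted motif instances, per-CpG bisulfite reports over
reprogramming timepoints, accessibility tracks, EMSA titration lane tables,
Spec-seq count tables — and emits machine-readable truth so downstream code
can be tested against known answers without any external download.

Reproducibility: a single global seed fans out through
``numpy.random.SeedSequence.spawn`` into independent substreams, one per
generator, so outputs are bit-identical per (config, seed) and adding a
generator does not perturb the others.

Defaults mirror the study conditions: 50 nM labeled probe titrated with
25-800 nM protein; a demethylating class that decays linearly from full
methylation to zero across reprogramming timepoints while the maintained
class stays at 100%; Boltzmann-weighted bound-band sampling for Spec-seq.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .equilibrium import BindingParameters, TitrationCondition, solve_species
from .motifs import CONSENSUS, GenomicInterval
from .methylome import CpgReport

__all__ = [
    "SimulationConfig",
    "substream",
    "make_genome",
    "simulate_methylome",
    "simulate_accessibility",
    "simulate_conservation",
    "simulate_titration",
    "simulate_specseq",
    "simulate_all",
]

# fixed substream indices: appending new generators must not shift old ones
_STREAMS = {
    "genome": 0,
    "methylome": 1,
    "titration": 2,
    "specseq": 3,
    "accessibility": 4,
    "conservation": 5,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one simulation component."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[name]])


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with study-condition defaults."""

    seed: int = 0
    # genome
    genome_length: int = 1_000_000
    gc_fraction: float = 0.42
    planted_motifs: Mapping[str, int] = field(
        default_factory=lambda: {"CpGpal": 50, "MORE": 20, "Octamer": 30}
    )
    chrom_name: str = "chrS"
    # peaks
    peak_width: int = 400
    # methylome
    n_sites: int = 400
    fraction_remains: float = 0.6
    coverage: int = 20
    timepoints: tuple[str, ...] = ("day0", "day3", "day6", "day8")
    # accessibility
    fraction_opens: float = 2 / 3
    open_coverage: float = 10.0
    closed_coverage: float = 0.5
    # titration (probe and protein series of the EMSA design)
    kd_half_site: float = 100.0
    omega: float = 5.0
    probe_total: float = 50.0
    protein_totals: tuple[float, ...] = (25.0, 50.0, 100.0, 200.0, 400.0, 800.0)
    noise_cv: float = 0.05
    # specseq
    specseq_pattern: str = "ATGNNNAT"
    specseq_depth: int = 100_000

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "fraction_remains", "fraction_opens"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(c < 0 for c in self.planted_motifs.values()):
            raise ValueError("motif counts must be >= 0")


def make_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[tuple[str, GenomicInterval]]]:
    """I.i.d. background genome with motifs planted at non-overlapping spots.

    Returns ``({chrom: sequence}, [(motif_name, interval), ...])``; truth
    intervals are 0-based half-open. Raises when the requested motifs cannot
    be packed without overlap.
    """
    rng = substream(config.seed, "genome")
    L = config.genome_length
    motif_bp = sum(len(CONSENSUS[m]) * n for m, n in config.planted_motifs.items())
    if L <= motif_bp * 2:
        raise ValueError(
            f"genome_length {L} too small for {motif_bp} bp of planted motifs"
        )

    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=L, p=probs)

    occupied = np.zeros(L, dtype=bool)
    truth: list[tuple[str, GenomicInterval]] = []
    for motif_name in sorted(config.planted_motifs):
        n = config.planted_motifs[motif_name]
        cons = CONSENSUS[motif_name].encode()
        w = len(cons)
        placed = 0
        attempts = 0
        while placed < n:
            attempts += 1
            if attempts > 1000 * max(n, 1):
                raise ValueError(f"infeasible packing for motif {motif_name}")
            start = int(rng.integers(0, L - w))
            if occupied[start : start + w].any():
                continue
            seq[start : start + w] = np.frombuffer(cons, dtype=np.uint8)
            occupied[max(0, start - w) : start + 2 * w] = True  # keep neighbors apart
            truth.append(
                (motif_name, GenomicInterval(config.chrom_name, start, start + w))
            )
            placed += 1
    truth.sort(key=lambda t: t[1].start)
    return {config.chrom_name: seq.tobytes().decode()}, truth


def simulate_methylome(
    sites: Sequence[GenomicInterval],
    config: SimulationConfig,
    site_ids: Sequence[str] | None = None,
) -> tuple[dict[str, CpgReport], pd.Series]:
    """Per-timepoint CpG reports for a cohort of motif sites.

    Every site starts fully methylated at its core CpG. The ``remains``
    class stays at fraction 1.0 at every timepoint; the ``demethylates``
    class decays linearly from 1.0 to 0.0 across the timepoints. Counts are
    binomial at the planted fraction with the configured coverage. Returns
    the reports and the truth labels (remains_methylated / demethylated).
    """
    rng = substream(config.seed, "methylome")
    if site_ids is None:
        site_ids = [f"site_{i}" for i in range(len(sites))]
    n = len(sites)
    n_remains = int(round(config.fraction_remains * n))
    labels = np.array(
        ["remains_methylated"] * n_remains + ["demethylated"] * (n - n_remains)
    )
    rng.shuffle(labels)
    truth = pd.Series(labels, index=pd.Index(site_ids, name="site_id"), name="truth")

    T = len(config.timepoints)
    reports: dict[str, CpgReport] = {}
    for t, label in enumerate(config.timepoints):
        rows = []
        for sid, site, cls in zip(site_ids, sites, labels):
            if cls == "remains_methylated":
                p = 1.0
            else:
                p = 1.0 - t / (T - 1) if T > 1 else 1.0
            core_left = site.start + len(site) // 2 - 1
            meth = int(rng.binomial(config.coverage, p)) if config.coverage else 0
            rows.append(
                {
                    "chrom": site.chrom,
                    "position": core_left,
                    "count_methylated": meth,
                    "count_unmethylated": config.coverage - meth,
                }
            )
        reports[label] = CpgReport(pd.DataFrame(rows))
    return reports, truth


def simulate_accessibility(
    sites: Sequence[GenomicInterval],
    config: SimulationConfig,
    genome_length: int | None = None,
) -> tuple[dict[str, dict[str, np.ndarray]], pd.Series]:
    """Coverage tracks per timepoint planting opens / remains_closed classes.

    All sites are closed at the first timepoint; the ``opens`` class jumps
    to open coverage at later timepoints. Truth labels are returned.
    """
    rng = substream(config.seed, "accessibility")
    L = genome_length or config.genome_length
    chrom = sites[0].chrom if sites else config.chrom_name
    n = len(sites)
    n_opens = int(round(config.fraction_opens * n))
    labels = np.array(["opens"] * n_opens + ["remains_closed"] * (n - n_opens))
    rng.shuffle(labels)
    ids = pd.Index([f"site_{i}" for i in range(n)], name="site_id")
    truth = pd.Series(labels, index=ids, name="truth")

    tracks: dict[str, dict[str, np.ndarray]] = {}
    for t, label in enumerate(config.timepoints):
        arr = np.full(L, config.closed_coverage)
        for site, cls in zip(sites, labels):
            if cls == "opens" and t > 0:
                lo = max(0, int(site.center) - 100)
                hi = min(L, int(site.center) + 100)
                arr[lo:hi] = config.open_coverage
        tracks[label] = {chrom: arr}
    return tracks, truth


def simulate_conservation(
    sites: Sequence[GenomicInterval],
    config: SimulationConfig,
    genome_length: int | None = None,
    dip_value: float = -1.0,
) -> dict[str, np.ndarray]:
    """Flat zero track with a planted dip at each site's central dinucleotide."""
    L = genome_length or config.genome_length
    chrom = sites[0].chrom if sites else config.chrom_name
    arr = np.zeros(L)
    for site in sites:
        c = int(site.center)
        arr[max(0, c - 1) : min(L, c + 1)] = dip_value
    return {chrom: arr}


def simulate_titration(
    params: BindingParameters,
    condition: TitrationCondition,
    noise_cv: float = 0.05,
    seed: int = 0,
    lane_scale: float = 1000.0,
) -> pd.DataFrame:
    """Lane table of band volumes from the equilibrium model plus gel noise.

    Band volume = model fraction x lane scale x lognormal(sd = noise_cv);
    ``noise_cv = 0`` reproduces the model fractions exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = substream(seed, "titration")
    rows = []
    for i, p_tot in enumerate(condition.protein_totals):
        fr = solve_species(params, p_tot, condition.probe_total)
        noise = (
            rng.lognormal(mean=0.0, sigma=noise_cv, size=3)
            if noise_cv > 0
            else np.ones(3)
        )
        rows.append(
            {
                "lane_id": f"lane_{i}",
                "protein_total_nM": p_tot,
                "intensity_free": fr.f_free * lane_scale * noise[0],
                "intensity_mon": fr.f_mon * lane_scale * noise[1],
                "intensity_dim": fr.f_dim * lane_scale * noise[2],
            }
        )
    return pd.DataFrame(rows)


def simulate_specseq(
    energies: pd.Series,
    depth: int = 100_000,
    seed: int = 0,
    condition: str = "unmethylated",
) -> pd.DataFrame:
    """Multinomial Spec-seq counts from planted relative energies (kT).

    Input counts are multinomial-uniform over the library at ``depth``;
    bound-band counts are multinomial with ``p_i proportional to
    exp(-ddG_i)``. Both dimer and monomer bands are drawn from the same
    energies here (the truth is per-band energies; pass a different series
    per band for band-specific landscapes).
    """
    rng = substream(seed, "specseq")
    seqs = list(energies.index)
    k = len(seqs)
    p_input = np.full(k, 1.0 / k)
    w = np.exp(-energies.to_numpy(dtype=float))
    p_bound = w / w.sum()
    return pd.DataFrame(
        {
            "sequence": seqs,
            "count_input": rng.multinomial(depth, p_input),
            "count_monomer": rng.multinomial(depth, p_bound),
            "count_dimer": rng.multinomial(depth, p_bound),
            "condition": condition,
        }
    )


def simulate_all(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate every input file plus truth.json; returns the truth dict.

    Writes genome.fa, motifs_truth.bed, peaks.bed, cpg_<timepoint>.tsv,
    accessibility_<timepoint>.bedGraph, conservation.bedGraph, lanes.tsv,
    specseq.tsv and truth.json under ``out_dir``.
    """
    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome, truth_sites = make_genome(config)
    cio.write_fasta(out / "genome.fa", genome)
    cio.write_bed(
        out / "motifs_truth.bed",
        [iv for _, iv in truth_sites],
        names=[m for m, _ in truth_sites],
    )

    # peaks centered on planted motifs
    L = config.genome_length
    half = config.peak_width // 2
    peaks = [
        GenomicInterval(
            iv.chrom, max(0, int(iv.center) - half), min(L, int(iv.center) + half)
        )
        for _, iv in truth_sites
    ]
    cio.write_bed(out / "peaks.bed", peaks)

    cpg_sites = [iv for m, iv in truth_sites if m == "CpGpal"]
    # methylation cohort: distinct evenly spaced 8-bp sites (each with its
    # own core CpG row in the report)
    w = len("ATGCGCAT")
    spacing = max((L - w) // (config.n_sites + 1), w)
    meth_sites = [
        GenomicInterval(config.chrom_name, p, p + w)
        for p in range(spacing, spacing * (config.n_sites + 1), spacing)
    ][: config.n_sites]
    cio.write_bed(out / "cohort_sites.bed", meth_sites)
    reports, meth_truth = simulate_methylome(meth_sites, config)
    for label, rep in reports.items():
        cio.write_cpg_report(out / f"cpg_{label}.tsv", rep)

    tracks, acc_truth = simulate_accessibility(cpg_sites, config)
    for label, track in tracks.items():
        cio.write_bedgraph(out / f"accessibility_{label}.bedGraph", track)
    cio.write_bedgraph(
        out / "conservation.bedGraph", simulate_conservation(cpg_sites, config)
    )

    params = BindingParameters(config.kd_half_site, config.omega)
    cond = TitrationCondition(config.probe_total, config.protein_totals)
    lanes = simulate_titration(params, cond, config.noise_cv, config.seed)
    lanes.to_csv(out / "lanes.tsv", sep="\t", index=False)

    from .specseq import enumerate_library

    lib = enumerate_library(config.specseq_pattern)
    rng = substream(config.seed, "specseq")
    planted = pd.Series(
        rng.uniform(0.0, 3.0, size=len(lib)), index=list(lib.variants)
    )
    if "ATGCGCAT" in planted.index:
        planted.loc["ATGCGCAT"] = -1.0  # tightest dimer binder by construction
    planted -= planted.min()
    counts = simulate_specseq(planted, config.specseq_depth, config.seed)
    counts.to_csv(out / "specseq.tsv", sep="\t", index=False)

    truth = {
        "seed": config.seed,
        "motifs": [
            {"name": m, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for m, iv in truth_sites
        ],
        "methylation_classes": meth_truth.to_dict(),
        "accessibility_classes": acc_truth.to_dict(),
        "titration": {
            "kd_half_site": config.kd_half_site,
            "omega": config.omega,
            "probe_total": config.probe_total,
        },
        "specseq_energies": planted.round(6).to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth
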