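"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of a :class:`SynthConfig` (including
its seed) and draws from its own pseudo-random stream derived from the
master seed, so adding one generator never perturbs another.  Every
generator emits a :class:`GroundTruth` alongside the data, which is
the oracle for parameter-recovery and classifier-accuracy tests.

What the defaults emulate: a CTD cast through a Gaussian turbidity
anomaly over a small absolute-normal background; a mock community of
500 genomes with log-normal coverage and the observed plume carriage
fractions (coxS 51%, [NiFe]-hydrogenase 38%, soxY 25%) planted as
exact carrier counts; cox operon fixtures of all four form classes
with motifs planted into motif-free random protein background; and a
multinomial transcriptome with known length-weighted expression rates.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import ctd
from .codh import (
    ACCESSORY_ROLES,
    FORM_I_PATTERN,
    FORM_II_MOTIF,
    AnnotatedGene,
    scan_motif,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "TAXA",
    "gen_ctd_cast",
    "gen_mock_community",
    "gen_operon_fixtures",
    "gen_transcriptome_counts",
    "flip_contig",
    "write_gff3",
    "write_fasta",
]

# Stream indices: one independent RNG stream per generator.
_STREAM_CTD, _STREAM_COMMUNITY, _STREAM_OPERONS, _STREAM_TRANSCRIPTOME = range(4)

#: Taxon labels assigned to mock-community genomes.
TAXA = ("SUP05", "Sulfurimonas", "SAR202", "SAR324", "other")
_TAXON_PROBS = (0.25, 0.25, 0.15, 0.10, 0.25)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    """Knobs of all four generators, with study-condition defaults."""

    seed: int = 0
    # mock community
    n_genomes: int = 500
    carriage_fractions: dict = field(
        default_factory=lambda: {"coxS": 0.51, "NiFe-hydrogenase": 0.38, "soxY": 0.25}
    )
    coverage_mu: float = math.log(3.0)  # log-normal location of genome coverage
    coverage_sigma: float = 0.5
    depth_noise: float = 0.0  # Poisson depth quantum; 0 = noise-free
    # CTD cast
    plume_depth: float = 2600.0  # m
    plume_width: float = 80.0  # Gaussian sigma, m
    plume_intensity: float = 0.5  # dNTU peak above background
    background_ntu: float = 0.005
    noise_sd: float = 0.002
    # operon fixtures
    n_per_class: int = 5
    n_singleton_contigs: int = 3
    # transcriptome
    n_features: int = 50
    n_housekeeping: int = 5
    library_size: int = 1_000_000
    multinomial_counts: bool = True  # False = noise-free expected counts

    def __post_init__(self) -> None:
        for fam, f in self.carriage_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"carriage fraction for {fam} outside [0,1]")
        if self.coverage_sigma < 0 or self.noise_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.plume_intensity < 0:
            raise ValueError("plume intensity must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Generative labels emitted alongside every synthetic dataset."""

    plume_categories: Optional[dict] = None  # bottle name -> category
    genome_complements: Optional[dict] = None  # family -> carrier genome ids
    genome_coverages: Optional[list] = None
    genome_taxa: Optional[list] = None
    carriage_fractions: Optional[dict] = None  # planted count fraction
    effective_fractions: Optional[dict] = None  # coverage-weighted fraction
    expression_rates: Optional[dict] = None  # feature -> true rate
    housekeeping: Optional[list] = None
    operon_labels: Optional[dict] = None  # contig -> form class
    singleton_contigs: Optional[list] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# CTD cast
# ---------------------------------------------------------------------------

def gen_ctd_cast(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """A vertical cast through a Gaussian turbidity anomaly.

    Observed dNTU is |Normal(background, noise_sd)| plus the anomaly;
    the true category of each bottle comes from the noise-free signal
    via the turbidity thresholds, with near-plume bottles resolved
    above/below by depth relative to the anomaly centre.
    """
    rng = config.rng(_STREAM_CTD)
    depths = config.plume_depth + np.arange(-600.0, 601.0, 60.0)
    anomaly = config.plume_intensity * np.exp(
        -((depths - config.plume_depth) ** 2) / (2.0 * config.plume_width**2)
    )
    signal = config.background_ntu + anomaly
    observed = np.abs(rng.normal(config.background_ntu, config.noise_sd, depths.size)) + anomaly
    names = [f"SIM{config.seed}_b{i + 1}" for i in range(depths.size)]
    truth_cat = {}
    for name, z, s in zip(names, depths, signal):
        cls = ctd.classify_turbidity(float(s))
        if cls == "near_plume":
            cls = "above_plume" if z <= config.plume_depth else "below_plume"
        truth_cat[name] = cls
    table = pd.DataFrame(
        {
            "name": names,
            "sample": [f"SIM{config.seed}CTD_b{i + 1}" for i in range(depths.size)],
            "depth": depths,
            "delta_ntu": np.round(observed, 4),
            "potential_temperature": np.round(rng.normal(2.7, 0.05, depths.size), 2),
            "salinity": np.round(rng.normal(34.93, 0.01, depths.size), 2),
        }
    )
    return table, GroundTruth(plume_categories=truth_cat)


# ---------------------------------------------------------------------------
# Mock community
# ---------------------------------------------------------------------------

def _noisy_depth(depth: np.ndarray, quantum: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson counting noise with a given depth quantum (0 = off)."""
    if quantum <= 0:
        return depth
    return rng.poisson(np.asarray(depth) / quantum) * quantum


def gen_mock_community(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Mock community with known gene complements and marker depths.

    Each of ``n_genomes`` genomes draws a log-normal coverage and one
    taxon label; each gene family is planted into exactly
    ``round(f * n)`` genomes (mock composition is known by design).
    The 16 single-copy markers each see the summed genome coverage, so
    genome equivalents recover total community coverage exactly on
    noise-free output.
    """
    if config.n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = config.rng(_STREAM_COMMUNITY)
    n = config.n_genomes
    coverages = rng.lognormal(config.coverage_mu, config.coverage_sigma, n)
    taxa = rng.choice(TAXA, size=n, p=_TAXON_PROBS)
    sample = f"mock_seed{config.seed}"
    total_cov = float(coverages.sum())

    marker_rows = []
    marker_depths = _noisy_depth(
        np.full(16, total_cov), config.depth_noise, rng
    )
    for i, d in enumerate(marker_depths):
        marker_rows.append({"sample": sample, "marker": f"rp{i + 1:02d}", "depth": float(d)})
    markers = pd.DataFrame(marker_rows)

    complements: dict[str, list[int]] = {}
    eff: dict[str, float] = {}
    planted: dict[str, float] = {}
    gene_rows = []
    for family, f in config.carriage_fractions.items():
        k = int(round(f * n))
        carriers = np.sort(rng.choice(n, size=k, replace=False))
        complements[family] = [int(c) for c in carriers]
        planted[family] = k / n
        eff[family] = float(coverages[carriers].sum() / total_cov)
        carrier_mask = np.zeros(n, dtype=bool)
        carrier_mask[carriers] = True
        for taxon in TAXA:
            sel = carrier_mask & (taxa == taxon)
            if not sel.any():
                continue
            depth = float(_noisy_depth(
                np.array([coverages[sel].sum()]), config.depth_noise, rng
            )[0])
            gene_rows.append(
                {"sample": sample, "gene_family": family, "taxon": taxon, "depth": depth}
            )
    genes = pd.DataFrame(gene_rows, columns=["sample", "gene_family", "taxon", "depth"])
    truth = GroundTruth(
        genome_complements=complements,
        genome_coverages=[float(c) for c in coverages],
        genome_taxa=[str(t) for t in taxa],
        carriage_fractions=planted,
        effective_fractions=eff,
    )
    return genes, markers, truth


# ---------------------------------------------------------------------------
# Operon fixtures
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein guaranteed free of both cox motifs (rejection)."""
    while True:
        seq = "".join(rng.choice(list(_AA), size=length))
        if scan_motif(seq) is None:
            return seq


def _plant(rng: np.random.Generator, length: int, motif: str) -> str:
    """Protein whose only motif hit is the planted one."""
    while True:
        seq = _random_protein(rng, length)
        pos = int(rng.integers(20, length - len(motif) - 10))
        planted = seq[:pos] + motif + seq[pos + len(motif):]
        hit = scan_motif(planted)
        if hit is not None and hit.motif == motif and hit.position == pos + 1:
            return planted


def flip_contig(genes: list[AnnotatedGene], contig_length: int) -> list[AnnotatedGene]:
    """Reverse a contig: coordinates mirrored, strands flipped.

    Protein translations are unchanged (the CDS still encodes the same
    product); classifications must be invariant under this transform.
    """
    flipped = [
        AnnotatedGene(
            contig=g.contig,
            start=contig_length - g.end + 1,
            end=contig_length - g.start + 1,
            strand="-" if g.strand == "+" else "+",
            product_role=g.product_role,
            protein_id=g.protein_id,
        )
        for g in genes
    ]
    return sorted(flipped, key=lambda g: g.start)


_CLASS_LAYOUTS = {
    # class -> (structural roles in transcription order, coxL motif kind)
    "form_II": (("coxS", "coxL", "coxM"), "form_II"),
    "putative_form_I": (("coxS", "coxL", "coxM"), "form_I"),
    "partial": (("coxL", "coxS"), "form_II"),
    "unknown": (("coxS", "coxL", "coxM"), None),
}


def gen_operon_fixtures(
    config: SynthConfig,
) -> tuple[list[AnnotatedGene], dict[str, str], GroundTruth]:
    """Planted cox operons of all four classes, plus reversed duplicates
    and singleton contigs beyond the gap threshold."""
    rng = config.rng(_STREAM_OPERONS)
    genes: list[AnnotatedGene] = []
    proteins: dict[str, str] = {}
    labels: dict[str, str] = {}
    singletons: list[str] = []

    def build_contig(contig: str, roles, motif_kind, extra_gap: int | None = None):
        """Lay out genes left-to-right on the + strand."""
        local: list[AnnotatedGene] = []
        cursor = 100
        for role in roles:
            length = int(rng.integers(250, 351))
            if role == "coxL":
                if motif_kind == "form_II":
                    seq = _plant(rng, length, FORM_II_MOTIF)
                elif motif_kind == "form_I":
                    wildcard = _AA[int(rng.integers(0, len(_AA)))]
                    seq = _plant(rng, length, f"AY{wildcard}CSFR")
                else:
                    seq = _random_protein(rng, length)
            else:
                seq = _random_protein(rng, length)
            pid = f"{contig}_{role}_{len(proteins):04d}"
            proteins[pid] = seq
            start = cursor
            end = start + 3 * length - 1
            local.append(AnnotatedGene(contig, start, end, "+", role, pid))
            gap = extra_gap if extra_gap is not None else int(rng.integers(50, 201))
            cursor = end + 1 + gap
        return local

    for cls, (roles, motif_kind) in _CLASS_LAYOUTS.items():
        for i in range(config.n_per_class):
            contig = f"ctg_{cls}_{i:02d}"
            local = build_contig(contig, roles, motif_kind)
            if cls == "form_II":
                # accessory genes elsewhere on the contig, beyond the gap rule
                cursor = local[-1].end + 2000
                for role in ACCESSORY_ROLES[:3]:
                    length = int(rng.integers(200, 301))
                    pid = f"{contig}_{role}_{len(proteins):04d}"
                    proteins[pid] = _random_protein(rng, length)
                    local.append(
                        AnnotatedGene(contig, cursor, cursor + 3 * length - 1, "+", role, pid)
                    )
                    cursor += 3 * length + 2000
            genes.extend(local)
            labels[contig] = cls
            # strand-flipped duplicate with its own protein ids
            rev_contig = contig + "_rev"
            rev_local = []
            for g in local:
                pid = g.protein_id + "_rev"
                proteins[pid] = proteins[g.protein_id]
                rev_local.append(
                    AnnotatedGene(rev_contig, g.start, g.end, g.strand, g.product_role, pid)
                )
            contig_length = max(g.end for g in rev_local) + 100
            genes.extend(flip_contig(rev_local, contig_length))
            labels[rev_contig] = cls

    for i in range(config.n_singleton_contigs):
        contig = f"ctg_singleton_{i:02d}"
        genes.extend(build_contig(contig, ("coxS", "coxL"), None, extra_gap=5000))
        singletons.append(contig)

    truth = GroundTruth(operon_labels=labels, singleton_contigs=singletons)
    return genes, proteins, truth


def write_gff3(genes: list[AnnotatedGene], path) -> None:
    """Write annotated genes as GFF3 CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            attrs = f"ID={g.protein_id};gene={g.product_role}"
            fh.write(
                f"{g.contig}\tventplume_synth\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def write_fasta(proteins: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def gen_transcriptome_counts(
    config: SynthConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Multinomial read counts over features with known expression rates.

    Read probability is proportional to rate * length, so TPM recovers
    the planted rates up to multinomial sampling error.
    """
    if config.n_features < 2:
        raise ValueError("need at least 2 features")
    rng = config.rng(_STREAM_TRANSCRIPTOME)
    n = config.n_features
    ids = [f"gene_{i + 1:03d}" for i in range(n)]
    lengths = rng.integers(300, 3001, size=n)
    rates = rng.lognormal(0.0, 1.0, size=n)
    p = rates * lengths
    p = p / p.sum()
    if config.multinomial_counts:
        counts = rng.multinomial(config.library_size, p).astype(float)
    else:
        counts = config.library_size * p  # noise-free expectation
    hk = sorted(rng.choice(ids, size=min(config.n_housekeeping, n), replace=False))
    table = pd.DataFrame(
        {"feature_id": ids, "length": lengths.astype(int), "count": counts}
    )
    truth = GroundTruth(
        expression_rates={i: float(r) for i, r in zip(ids, rates)},
        housekeeping=[str(h) for h in hk],
    )
    return table, truth
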