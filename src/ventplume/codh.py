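"""Form classification of aerobic CO-dehydrogenase (cox) operons.

The molybdenum-hydroxylase CO dehydrogenase occurs in two forms that
differ in the active-site loop of the large subunit (coxL): the
canonical high-activity form I carries an AYxCSFR loop, while the
form II variant carries AYRGAGR.  Form assignment here combines the
coxL motif with gene-cluster evidence: cox genes on one contig and
strand within 500 bp of each other form a candidate operon, whose
structural subunit order (S/M/L, in transcription direction) and
accessory-gene complement (coxD/E/F/G, searched genome-wide since
form II operons keep no consensus accessory arrangement) are reported
as supporting evidence.

Decision order: an operon missing any structural subunit is ``partial``
regardless of motif; otherwise the coxL motif decides ``form_II`` /
``putative_form_I`` / ``unknown``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FORM_II_MOTIF",
    "FORM_I_PATTERN",
    "OPERON_GAP_BP",
    "STRUCTURAL_ROLES",
    "ACCESSORY_ROLES",
    "AnnotatedGene",
    "CoxOperon",
    "MotifMatch",
    "CodhClassification",
    "AlphabetError",
    "MissingProteinError",
    "scan_motif",
    "detect_operons",
    "classify_operon",
    "classify_genome",
    "read_gff3",
    "read_proteins",
    "run_codh",
]

#: Form II active-site loop in coxL.
FORM_II_MOTIF = "AYRGAGR"
#: Form I active-site loop (one wildcard position), regex.
FORM_I_PATTERN = r"AY[A-Z]CSFR"
#: Maximum intergenic gap inside one operon, bp.
OPERON_GAP_BP = 500

STRUCTURAL_ROLES = ("coxS", "coxM", "coxL")
ACCESSORY_ROLES = ("coxD", "coxE", "coxF", "coxG")
_COX_ROLES = set(STRUCTURAL_ROLES) | set(ACCESSORY_ROLES)

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class AlphabetError(ValueError):
    """A protein sequence with characters outside the amino-acid alphabet."""


class MissingProteinError(KeyError):
    """An operon has a coxL gene but no translation was supplied."""


@dataclass(frozen=True)
class AnnotatedGene:
    """One annotated CDS: 1-based inclusive coordinates on a contig."""

    contig: str
    start: int
    end: int
    strand: str
    product_role: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for {self.protein_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or - for {self.protein_id}")


@dataclass(frozen=True)
class MotifMatch:
    form: str  # "form_II" or "form_I"
    motif: str  # matched substring
    position: int  # 1-based in the protein


@dataclass(frozen=True)
class CoxOperon:
    """Cox genes on one contig/strand in transcription order."""

    genes: tuple[AnnotatedGene, ...]
    structural_order: tuple[str, ...]  # letters over {S, M, L}
    accessory_present: frozenset[str]  # letters over {D, E, F, G}

    @property
    def contig(self) -> str:
        return self.genes[0].contig

    @property
    def strand(self) -> str:
        return self.genes[0].strand

    @property
    def order_string(self) -> str:
        return "-".join(self.structural_order)


@dataclass(frozen=True)
class CodhClassification:
    form: str  # form_II | putative_form_I | partial | unknown
    motif_evidence: Optional[MotifMatch]
    order_evidence: str
    accessory_evidence: frozenset[str] = field(default_factory=frozenset)


def scan_motif(
    protein_sequence: str,
    form_ii_motif: str = FORM_II_MOTIF,
    form_i_pattern: str = FORM_I_PATTERN,
) -> Optional[MotifMatch]:
    """Scan a coxL translation for the form-discriminating loop motifs.

    The earliest match along the sequence wins; at any one position the
    exact form II motif is checked before the form I pattern.  Position
    is 1-based.  ``X`` is permitted in the sequence and matches the
    form I wildcard only.
    """
    seq = protein_sequence.upper()
    illegal = set(seq) - _AA_ALPHABET
    if illegal:
        raise AlphabetError(f"illegal amino-acid characters {sorted(illegal)}")
    ii = seq.find(form_ii_motif)
    m = re.search(form_i_pattern, seq)
    i = m.start() if m else -1
    candidates = []
    if ii >= 0:
        candidates.append((ii, MotifMatch("form_II", form_ii_motif, ii + 1)))
    if i >= 0:
        candidates.append((i + 0.5, MotifMatch("form_I", m.group(0), i + 1)))
    if not candidates:
        return None
    return min(candidates, key=lambda t: t[0])[1]


def _role_letter(role: str) -> str:
    return role[-1].upper()


def detect_operons(
    genes: Iterable[AnnotatedGene],
    gap_bp: int = OPERON_GAP_BP,
    include_singletons: bool = False,
):
    """Group cox genes into candidate operons.

    Genes with cox roles on the same contig and strand whose intergenic
    gaps are at most ``gap_bp`` form a cluster; clusters with at least
    two structural subunits become operons, listed in transcription
    order (coordinate order, reversed on the minus strand).  With
    ``include_singletons`` the leftover cox genes are returned too.
    """
    cox = [g for g in genes if g.product_role in _COX_ROLES]
    clusters: list[list[AnnotatedGene]] = []
    by_key: dict[tuple[str, str], list[AnnotatedGene]] = {}
    for g in cox:
        by_key.setdefault((g.contig, g.strand), []).append(g)
    for (_, strand), members in sorted(by_key.items()):
        members.sort(key=lambda g: g.start)
        current = [members[0]]
        for g in members[1:]:
            if g.start - current[-1].end - 1 <= gap_bp:
                current.append(g)
            else:
                clusters.append(current)
                current = [g]
        clusters.append(current)

    operons: list[CoxOperon] = []
    singletons: list[AnnotatedGene] = []
    for cluster in clusters:
        structural = [g for g in cluster if g.product_role in STRUCTURAL_ROLES]
        if len(structural) < 2:
            singletons.extend(cluster)
            continue
        ordered = cluster if cluster[0].strand == "+" else list(reversed(cluster))
        operons.append(
            CoxOperon(
                genes=tuple(ordered),
                structural_order=tuple(
                    _role_letter(g.product_role)
                    for g in ordered
                    if g.product_role in STRUCTURAL_ROLES
                ),
                accessory_present=frozenset(
                    _role_letter(g.product_role)
                    for g in ordered
                    if g.product_role in ACCESSORY_ROLES
                ),
            )
        )
    operons.sort(key=lambda o: (o.contig, o.genes[0].start))
    if include_singletons:
        return operons, singletons
    return operons


def classify_operon(
    operon: CoxOperon,
    proteins: Mapping[str, str],
    genome_accessories: Optional[frozenset[str]] = None,
) -> CodhClassification:
    """Assign a CODH form to one operon.

    (1) missing any of S/M/L -> ``partial``; (2) coxL carries the
    form II motif -> ``form_II``; (3) coxL carries the form I motif ->
    ``putative_form_I``; (4) otherwise ``unknown``.  Accessory genes
    (operon-local plus any supplied genome-wide set) are evidence only
    and never change the form call.
    """
    accessories = operon.accessory_present | (genome_accessories or frozenset())
    motif: Optional[MotifMatch] = None
    if "L" in operon.structural_order:
        l_gene = next(g for g in operon.genes if g.product_role == "coxL")
        translation = proteins.get(l_gene.protein_id)
        if translation is None:
            raise MissingProteinError(
                f"no translation for coxL protein {l_gene.protein_id}"
            )
        motif = scan_motif(translation)

    missing = set("SML") - set(operon.structural_order)
    if missing:
        form = "partial"
    elif motif is not None and motif.form == "form_II":
        form = "form_II"
    elif motif is not None and motif.form == "form_I":
        form = "putative_form_I"
    else:
        form = "unknown"
    return CodhClassification(
        form=form,
        motif_evidence=motif,
        order_evidence=operon.order_string,
        accessory_evidence=accessories,
    )


def classify_genome(
    genes: Sequence[AnnotatedGene],
    proteins: Mapping[str, str],
    gap_bp: int = OPERON_GAP_BP,
) -> list[tuple[CoxOperon, CodhClassification]]:
    """Detect and classify every cox operon in one annotation set.

    The accessory-gene search spans the whole input (form II accessory
    genes commonly lie elsewhere on the genome).
    """
    genome_acc = frozenset(
        _role_letter(g.product_role)
        for g in genes
        if g.product_role in ACCESSORY_ROLES
    )
    return [
        (op, classify_operon(op, proteins, genome_accessories=genome_acc))
        for op in detect_operons(genes, gap_bp=gap_bp)
    ]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_PRODUCT_ROLE_PATTERNS = (
    (re.compile(r"large subunit", re.I), "coxL"),
    (re.compile(r"medium subunit", re.I), "coxM"),
    (re.compile(r"small subunit", re.I), "coxS"),
)


def _infer_role(attrs) -> str:
    for key in ("gene", "Name"):
        for value in attrs.get(key, []):
            m = re.fullmatch(r"cox([SMLDEFG])", value, flags=re.I)
            if m:
                return "cox" + m.group(1).upper()
    for value in attrs.get("product", []):
        if "dehydrogenase" in value.lower() and "monoxide" in value.lower():
            for pattern, role in _PRODUCT_ROLE_PATTERNS:
                if pattern.search(value):
                    return role
    return "other"


def read_gff3(path) -> list[AnnotatedGene]:
    """Load CDS features from a GFF3 file into annotated genes."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.all_features(featuretype="CDS", order_by=("seqid", "start")):
        pid = (feat.attributes.get("protein_id") or feat.attributes.get("ID") or [feat.id])[0]
        genes.append(
            AnnotatedGene(
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product_role=_infer_role(feat.attributes),
                protein_id=pid,
            )
        )
    return genes


def read_proteins(path) -> dict[str, str]:
    """Load a protein FASTA into a protein_id -> sequence map."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_codh(gff_path, faa_path, gap_bp: int = OPERON_GAP_BP) -> pd.DataFrame:
    """File-based pipeline: one classified row per detected operon."""
    genes = read_gff3(gff_path)
    proteins = read_proteins(faa_path)
    rows = []
    for op, cls in classify_genome(genes, proteins, gap_bp=gap_bp):
        rows.append(
            {
                "contig": op.contig,
                "strand": op.strand,
                "n_genes": len(op.genes),
                "structural_order": op.order_string,
                "form": cls.form,
                "motif": cls.motif_evidence.motif if cls.motif_evidence else "none",
                "motif_position": (
                    cls.motif_evidence.position if cls.motif_evidence else pd.NA
                ),
                "accessories": "".join(sorted(cls.accessory_evidence)) or "none",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "strand", "n_genes", "structural_order",
            "form", "motif", "motif_position", "accessories",
        ],
    )
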