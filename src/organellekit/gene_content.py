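"""Gene-content profiling of organelle genomes.

Classifies every catalog gene as intact / pseudogene / lost against a
reference catalog, aggregates counts by functional category, compares
species content matrices, and places a plastome on the five-stage
degradation trajectory observed in parasitic plants (Photosynthetic ->
Degradation I -> Stationary -> Degradation II -> Absent).

A pseudogene is an annotated gene that is abnormally short relative to its
reference, whose translation terminates before the final codon of the
aligned reference span, or whose nucleotide identity to the reference falls
below a divergence threshold.  A gene with no homologous segment at all is
lost.  Structural RNA genes (trn/rrn) are exempt from the stop-codon test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import best_local_hit, evalue, translate

# --------------------------------------------------------------------------
# controlled vocabularies

PLASTID_CATEGORIES = (
    "psa", "psb", "pet", "ndh", "rpo", "atp", "rbcL",
    "rps", "rpl", "trn", "rrn", "ycf", "other",
)

MITO_CORE_CATEGORIES = ("atp", "ccm", "cob", "cox", "nad", "matR", "mttB")
MITO_VARIABLE_CATEGORIES = ("rps", "rpl", "sdh")

#: The ~24 mitochondrial genes nearly universal across angiosperms.
DEFAULT_MITO_CORE = frozenset(
    [
        "atp1", "atp4", "atp6", "atp8", "atp9",
        "ccmB", "ccmC", "ccmFc", "ccmFn",
        "cob", "cox1", "cox2", "cox3",
        "matR", "mttB",
        "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
    ]
)

#: Mitochondrial genes frequently lost across angiosperms.
DEFAULT_MITO_VARIABLE = frozenset(
    [
        "rps1", "rps2", "rps3", "rps4", "rps7", "rps10", "rps11", "rps12",
        "rps13", "rps14", "rps19",
        "rpl2", "rpl5", "rpl10", "rpl16",
        "sdh3", "sdh4",
    ]
)


def categorize(name: str, genome: str = "plastid") -> str:
    """Functional category of a gene symbol.

    Plastid symbols map onto the standard prefix vocabulary (psa, psb, pet,
    ndh, rpo, atp, rps, rpl, trn, rrn, ycf, rbcL, other); mitochondrial
    symbols onto core vs variable gene families.
    """
    base = name.split("-")[0] if name.startswith("trn") else name
    if genome == "mito":
        for prefix in ("atp", "ccm", "nad", "sdh", "rps", "rpl"):
            if base.startswith(prefix):
                return prefix
        for exact in ("cob", "matR", "mttB"):
            if base == exact:
                return exact
        for prefix in ("cox", "trn", "rrn"):
            if base.startswith(prefix):
                return prefix
        return "other"
    if base == "rbcL":
        return "rbcL"
    for prefix in ("psa", "psb", "pet", "ndh", "rpo", "atp", "rps", "rpl",
                   "trn", "rrn", "ycf"):
        if base.startswith(prefix):
            return prefix
    return "other"


def is_structural_rna(name: str) -> bool:
    return name.startswith("trn") or name.startswith("rrn")


# --------------------------------------------------------------------------
# domain types


class Status(str, enum.Enum):
    INTACT = "intact"
    PSEUDOGENE = "pseudogene"
    LOST = "lost"


class Reason(str, enum.Enum):
    OK = "ok"
    PREMATURE_STOP = "premature_stop"
    TOO_SHORT = "too_short"
    EXCESS_DIVERGENCE = "excess_divergence"
    NO_HIT = "no_hit"


class DegradationStage(enum.IntEnum):
    """Ordered stages of plastome decay in parasitic plants."""

    PHOTOSYNTHETIC = 0
    DEGRADATION_I = 1
    STATIONARY = 2
    DEGRADATION_II = 3
    ABSENT = 4

    @property
    def label(self) -> str:
        return {
            0: "Photosynthetic",
            1: "Degradation I",
            2: "Stationary",
            3: "Degradation II",
            4: "Absent",
        }[int(self)]


@dataclass(frozen=True)
class GeneStatus:
    status: Status
    reason: Reason

    def __post_init__(self):
        if (self.status is Status.LOST) != (self.reason is Reason.NO_HIT):
            raise ValueError("lost <=> reason no_hit")
        if (self.status is Status.INTACT) != (self.reason is Reason.OK):
            raise ValueError("intact <=> reason ok")


@dataclass
class GeneRecord:
    """One annotated gene: symbol, category, location and sequence."""

    name: str
    category: str
    replicon: str
    start: int  # 0-based
    end: int  # half-open
    strand: int = 1
    copy: int = 1
    sequence: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.name}: empty interval")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1/-1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneCatalog:
    """Annotated genes of one organelle genome (possibly multi-replicon)."""

    genes: list[GeneRecord] = field(default_factory=list)
    replicon_lengths: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)

    def symbols(self) -> set[str]:
        return {g.name for g in self.genes}

    def by_name(self, name: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.name == name]

    def validate(self) -> None:
        seen = set()
        for g in self.genes:
            key = (g.replicon, g.name, g.copy)
            if key in seen:
                raise ValueError(f"duplicate gene copy {key}")
            seen.add(key)
            n = self.replicon_lengths.get(g.replicon)
            if n is not None and not (0 <= g.start < g.end <= n):
                raise ValueError(f"{g.name}: coordinates outside {g.replicon}")

    # -- GFF3 + FASTA round trip ------------------------------------------

    def write_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for rep, n in self.replicon_lengths.items():
            lines.append(f"##sequence-region {rep} 1 {n}")
        for g in sorted(self.genes, key=lambda g: (g.replicon, g.start)):
            ftype = {"trn": "tRNA", "rrn": "rRNA"}.get(g.category, "gene")
            attrs = (
                f"ID={g.name}.{g.copy};Name={g.name};"
                f"category={g.category};copy={g.copy}"
            )
            lines.append(
                "\t".join(
                    [
                        g.replicon, "organellekit", ftype,
                        str(g.start + 1), str(g.end), ".",
                        "+" if g.strand == 1 else "-", ".", attrs,
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_gff3(
        cls, path: str | Path, sequences: dict[str, str] | None = None
    ) -> "GeneCatalog":
        replicon_lengths: dict[str, int] = {}
        genes = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("##sequence-region"):
                _, rep, _, n = line.split()
                replicon_lengths[rep] = int(n)
                continue
            if not line or line.startswith("#"):
                continue
            rep, _, _, start, end, _, strand, _, attrs = line.split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
            start0, end0 = int(start) - 1, int(end)
            seq = None
            if sequences is not None and rep in sequences:
                seq = sequences[rep][start0:end0]
                if strand == "-":
                    seq = str(Seq(seq).reverse_complement())
            genes.append(
                GeneRecord(
                    name=fields["Name"],
                    category=fields.get("category", categorize(fields["Name"])),
                    replicon=rep,
                    start=start0,
                    end=end0,
                    strand=1 if strand == "+" else -1,
                    copy=int(fields.get("copy", 1)),
                    sequence=seq,
                )
            )
        return cls(genes=genes, replicon_lengths=replicon_lengths)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def read_genbank(path: str | Path) -> GeneCatalog:
    """Gene catalog from a GenBank flat file (gene/tRNA/rRNA features)."""
    genes = []
    lengths = {}
    counts: dict[tuple[str, str], int] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        lengths[rec.id] = len(rec.seq)
        for feat in rec.features:
            if feat.type not in ("gene", "CDS", "tRNA", "rRNA"):
                continue
            name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
            if feat.type == "CDS" and any(
                g.name == name and g.replicon == rec.id for g in genes
            ):
                continue  # gene feature already captured
            key = (rec.id, name)
            counts[key] = counts.get(key, 0) + 1
            genes.append(
                GeneRecord(
                    name=name,
                    category=categorize(name),
                    replicon=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand=feat.location.strand or 1,
                    copy=counts[key],
                    sequence=str(feat.extract(rec.seq)),
                )
            )
    return GeneCatalog(genes=genes, replicon_lengths=lengths)


# --------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds for gene-status classification.

    tau_len: minimum observed/reference length fraction for a functional gene.
    tau_id: minimum nucleotide identity (global alignment) to the reference.
    evalue_cutoff: homology significance gate; below it a segment counts as
    a hit at all, mirroring the transfer-scan cutoff.
    """

    tau_len: float = 0.5
    tau_id: float = 0.6
    evalue_cutoff: float = 1e-10
    k: int = 13


_GLOBAL_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-0.5,
)


def global_identity(a: str, b: str) -> float:
    """Identity of the optimal global alignment, over the longer sequence."""
    aln = _GLOBAL_ALIGNER.align(a, b)[0]
    return aln.counts().identities / max(len(a), len(b))


def classify_gene(
    observed: str | None,
    reference: str,
    params: ClassifyParams = ClassifyParams(),
    structural_rna: bool = False,
) -> GeneStatus:
    """Status of one observed gene copy against its reference CDS.

    lost: no homologous segment at the significance cutoff.
    pseudogene: homologous but abnormally short, prematurely terminated
    (protein genes only), or excessively diverged.
    """
    if not reference:
        raise ValueError("empty reference")
    if any(c not in "ACGTNacgtn" for c in reference) or (
        observed and any(c not in "ACGTNacgtn" for c in observed)
    ):
        raise ValueError("non-nucleotide characters")
    if not structural_rna and len(reference) % 3 != 0:
        raise ValueError("protein-gene reference length must be divisible by 3")
    if observed is None or not observed:
        return GeneStatus(Status.LOST, Reason.NO_HIT)

    hit = best_local_hit(reference, observed, k=params.k)
    if hit is None or evalue(hit.score, len(reference), len(observed)) >= params.evalue_cutoff:
        return GeneStatus(Status.LOST, Reason.NO_HIT)

    if len(observed) < params.tau_len * len(reference):
        return GeneStatus(Status.PSEUDOGENE, Reason.TOO_SHORT)

    if not structural_rna:
        # Translate the observed copy in the reading frame implied by the
        # alignment to the reference; any stop strictly before the final
        # codon of the aligned reference span marks premature termination.
        frame = (hit.sstart - hit.qstart) % 3
        aa = translate(observed[frame:])
        last_codon = (len(reference) // 3) - 1
        internal = aa[: min(len(aa), last_codon)]
        if "*" in internal:
            return GeneStatus(Status.PSEUDOGENE, Reason.PREMATURE_STOP)

    if global_identity(observed, reference) < params.tau_id:
        return GeneStatus(Status.PSEUDOGENE, Reason.EXCESS_DIVERGENCE)
    return GeneStatus(Status.INTACT, Reason.OK)


def classify_catalog(
    catalog: GeneCatalog,
    reference: dict[str, str],
    params: ClassifyParams = ClassifyParams(),
    genome: str = "plastid",
) -> pd.DataFrame:
    """Classify every reference gene against the annotated catalog.

    Reference genes with no annotated copy are reported lost.  Returns one
    row per (gene, copy) with columns gene, copy, category, status, reason.
    """
    rows = []
    for name in sorted(reference):
        copies = catalog.by_name(name)
        if not copies:
            rows.append(
                {
                    "gene": name,
                    "copy": 0,
                    "category": categorize(name, genome),
                    "status": Status.LOST.value,
                    "reason": Reason.NO_HIT.value,
                }
            )
            continue
        for rec in sorted(copies, key=lambda g: g.copy):
            gs = classify_gene(
                rec.sequence,
                reference[name],
                params,
                structural_rna=is_structural_rna(name),
            )
            rows.append(
                {
                    "gene": name,
                    "copy": rec.copy,
                    "category": rec.category,
                    "status": gs.status.value,
                    "reason": gs.reason.value,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# aggregation

_STATUS_RANK = {Status.INTACT.value: 0, Status.PSEUDOGENE.value: 1, Status.LOST.value: 2}

#: Collapsed categories used in summary tables (photosynthesis and
#: housekeeping protein genes other than rps/rpl lumped as "other").
SUMMARY_CATEGORIES = ("trn", "rrn", "rps", "rpl", "other")


def collapse_copies(classified: pd.DataFrame) -> pd.DataFrame:
    """One row per gene symbol; the better status among copies wins.

    Genes duplicated across the two plastome inverted repeats are reported
    once; only if the copies differ does the less degraded one count.
    """
    df = classified.copy()
    df["_rank"] = df["status"].map(_STATUS_RANK)
    df = df.sort_values(["gene", "_rank", "copy"]).drop_duplicates("gene")
    return df.drop(columns="_rank").sort_values("gene").reset_index(drop=True)


def count_by_status(
    classified: pd.DataFrame,
    per_symbol: bool = True,
    summary: bool = False,
) -> dict:
    """Status totals plus a per-category breakdown of each status.

    per_symbol collapses duplicated copies (plastome convention); with
    per_symbol=False each annotated copy counts (mitogenome convention,
    where duplicated genes are genuinely separate loci).  ``summary``
    collapses categories to trn/rrn/rps/rpl/other.
    """
    df = collapse_copies(classified) if per_symbol else classified
    if summary:
        df = df.copy()
        df["category"] = [
            c if c in SUMMARY_CATEGORIES else "other" for c in df["category"]
        ]
    totals = df["status"].value_counts().to_dict()
    breakdown: dict[str, dict[str, int]] = {}
    for (status, cat), n in df.groupby(["status", "category"]).size().items():
        breakdown.setdefault(status, {})[cat] = int(n)
    out = {s.value: int(totals.get(s.value, 0)) for s in Status}
    out["by_category"] = breakdown
    out["total"] = int(len(df))
    return out


def check_core_retention(
    catalog: GeneCatalog | pd.DataFrame,
    core_list: frozenset[str] | set[str] = DEFAULT_MITO_CORE,
    variable_list: frozenset[str] | set[str] = DEFAULT_MITO_VARIABLE,
) -> dict:
    """Retention of the mitochondrial core gene set.

    Accepts an annotated catalog (presence = annotated) or a classification
    table (presence = status != lost).  Variable-gene losses are reported
    separately; they carry no parasitism signal but are listed for context.
    """
    if not core_list:
        raise ValueError("core_list empty")
    if isinstance(catalog, pd.DataFrame):
        present = set(
            catalog.loc[catalog["status"] != Status.LOST.value, "gene"]
        )
    else:
        present = catalog.symbols()
    core_missing = set(core_list) - present
    return {
        "core_present": len(core_list) - len(core_missing),
        "core_total": len(core_list),
        "core_missing": sorted(core_missing),
        "variable_missing": sorted(set(variable_list) - present),
    }


# --------------------------------------------------------------------------
# degradation staging

#: Categories whose combined intact-gene count defines the "photosynthesis
#: effectively gone" condition of the Stationary stage.
_PHOTO_CATEGORIES = ("psa", "psb", "pet")
#: Housekeeping categories whose decay marks Degradation II.  rbcL is not
#: decisive on its own: it is a single-gene category that is frequently
#: already lost during earlier stages in holoparasites.
_LATE_CATEGORIES = ("atp", "rps", "rpl")


def profile_from_classification(classified: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Per-category (intact count, total) profile from a classified table."""
    df = collapse_copies(classified)
    profile = {}
    for cat, sub in df.groupby("category"):
        profile[cat] = (
            int((sub["status"] == Status.INTACT.value).sum()),
            int(len(sub)),
        )
    return profile


def assign_stage(profile: dict[str, tuple[int, int]] | None) -> DegradationStage:
    """Place a plastome on the five-stage degradation trajectory.

    The rule table is monotone: degrading one more gene can only keep the
    stage or move it later.  ``profile`` maps functional category to
    (intact count, total count); ``None`` (no plastome) means Absent.
    """
    if profile is None:
        return DegradationStage.ABSENT

    def frac(cat: str) -> float:
        intact, total = profile.get(cat, (0, 0))
        if total == 0:
            return 1.0  # category absent from the reference: no signal
        if not 0 <= intact <= total:
            raise ValueError(f"bad counts for {cat}")
        return intact / total

    def intact_count(cat: str) -> int:
        return profile.get(cat, (0, 0))[0]

    if any(frac(c) < 0.5 for c in _LATE_CATEGORIES):
        return DegradationStage.DEGRADATION_II
    photo_intact = sum(intact_count(c) for c in _PHOTO_CATEGORIES)
    if frac("ndh") == 0 and frac("rpo") == 0 and photo_intact <= 1:
        return DegradationStage.STATIONARY
    if any(frac(c) < 1.0 for c in ("psa", "psb", "pet", "rpo")):
        return DegradationStage.DEGRADATION_I
    return DegradationStage.PHOTOSYNTHETIC


# --------------------------------------------------------------------------
# cross-species comparison


def compare_content(matrix: pd.DataFrame, a: str, b: str) -> dict:
    """Lost/pseudogene counts of two species and b as a percentage of a.

    ``matrix`` is species x gene with cell values intact/pseudogene/lost
    (or NA for genes absent from a species' reference).  Ratios against a
    zero baseline are reported as None rather than raising.
    """
    for sp in (a, b):
        if sp not in matrix.index:
            raise KeyError(f"unknown species {sp!r}")

    def counts(sp: str) -> tuple[int, int]:
        row = matrix.loc[sp]
        return (
            int((row == Status.LOST.value).sum()),
            int((row == Status.PSEUDOGENE.value).sum()),
        )

    lost_a, pseudo_a = counts(a)
    lost_b, pseudo_b = counts(b)

    def pct(x: int, base: int) -> float | None:
        return None if base == 0 else round(100.0 * x / base, 1)

    return {
        "lost_a": lost_a,
        "lost_b": lost_b,
        "lost_pct_of_a": pct(lost_b, lost_a),
        "pseudo_a": pseudo_a,
        "pseudo_b": pseudo_b,
        "pseudo_pct_of_a": pct(pseudo_b, pseudo_a),
    }
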