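"""Synthetic organelle-genome fixtures with the structural properties the
analysis assumes.

The default fixture emulates the organelle genomes of a holoparasitic
broomrape-family plant: a severely reduced quadripartite plastome (30,072
bp LSC + 480 bp SSC + two 32,761 bp inverted repeats; 68 intact genes, 11
pseudogenes, 40 losses against a photosynthetic reference), a
three-chromosome mitogenome (87,933 / 303,254 / 241,909 bp; 75 local
genes) carrying nine planted plastid-derived fragments of eight genes, a
set of bootstrap-annotated donor trees whose classifier outcomes tally
four intracellular transfers, three horizontal transfers and two
undetermined fragments, and expression tables reproducing the observed
photosynthesis- and chlorophyll-pathway presence patterns.

Everything is generated from a single integer seed; identical spec + seed
give byte-identical outputs.  Filler sequence is i.i.d. uniform nucleotide
at roughly the GC content of each genome, which avoids spurious homology;
reference gene lengths default to 300 bp because real lengths are
irrelevant to the logic under test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._align import revcomp
from .gene_content import (
    GeneCatalog,
    GeneRecord,
    categorize,
    is_structural_rna,
    write_fasta,
)
from .pathway_completeness import ExpressionEvidence, load_builtin
from .plastome_structure import PlastomePartition

# ==========================================================================
# reference gene rosters (the non-parasite donor panel)

INTACT_TRN = (
    "trnA-UGC", "trnC-GCA", "trnD-GUC", "trnE-UUC", "trnF-GAA", "trnfM-CAU",
    "trnG-GCC", "trnG-UCC", "trnH-GUG", "trnI-CAU", "trnI-GAU", "trnK-UUU",
    "trnL-CAA", "trnL-UAA", "trnL-UAG", "trnM-CAU", "trnN-GUU", "trnP-UGG",
    "trnQ-UUG", "trnR-ACG", "trnR-CCG", "trnR-UCU", "trnS-GCU", "trnS-GGA",
    "trnS-UGA", "trnT-GGU", "trnT-UGU", "trnV-UAC", "trnW-CCA", "trnY-GUA",
    "trnfM-CAA",
)

#: The duplicated plastid rRNA operon is represented as eight distinct
#: symbols (each still carried by both inverted repeats) so that
#: per-symbol reporting matches the conventional per-operon rRNA count.
INTACT_RRN = (
    "rrn4.5", "rrn4.5b", "rrn5", "rrn5b", "rrn16", "rrn16b", "rrn23", "rrn23b",
)

INTACT_RPS = (
    "rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12", "rps14",
    "rps18", "rps19",
)
INTACT_RPL = ("rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl32", "rpl33")
INTACT_OTHER = (
    "ycf1", "ycf2", "accD", "matK", "infA", "clpP", "psbA",
    "atpA", "atpB", "atpF", "atpH", "atpI",
)

PSEUDOGENES = (
    "rps16", "psbI", "rpoB", "psbD", "atpE", "petB", "rpoA", "rpl23",
    "ycf15", "ndhB", "rps15",
)

LOST_GENES = (
    "psaA", "psaB", "psaC", "psaI", "psaJ",
    "psbB", "psbC", "psbE", "psbF", "psbH", "psbJ", "psbK", "psbL",
    "psbM", "psbN", "psbT", "psbZ",
    "ndhA", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH", "ndhI",
    "ndhJ", "ndhK",
    "petA", "petD", "petG", "petL", "petN",
    "ycf3", "ycf4", "ccsA", "cemA", "rbcL", "rpoC1", "rpoC2",
    "trnV-GAC",
)

PLASTID_REFERENCE_GENES = tuple(
    sorted(
        INTACT_TRN + INTACT_RRN + INTACT_RPS + INTACT_RPL + INTACT_OTHER
        + PSEUDOGENES + LOST_GENES
    )
)

#: Genes residing in the inverted repeats of the reduced plastome (each is
#: annotated twice, once per repeat).
IR_GENES = (
    "ndhB", "ycf15", "ycf1", "ycf2", "rpl14", "rpl16", "rpl22", "rps3",
    "rps19",
) + INTACT_RRN
SSC_GENES = ("rpl32",)

#: Reference gene lengths in bp (default 300 for protein genes).
GENE_LENGTHS = {"trn": 80, "rrn": 120}
LONG_GENES = {"ycf1": 900, "ycf2": 900}

# mitochondrial rosters --------------------------------------------------

MITO_PCG_BY_CHROM = (
    ("atp1", "cob", "cox1", "nad1"),
    (
        "atp4", "atp6", "atp8", "atp9", "ccmB", "ccmC", "ccmFc", "ccmFn",
        "cox2", "cox3", "matR", "mttB", "nad2", "nad3", "nad4", "nad4L",
    ),
    (
        "nad5", "nad6", "nad7", "nad9", "rps1", "rps3", "rps4", "rps7",
        "rps10", "rps12", "rps13", "rps14", "rpl2", "rpl5", "rpl10",
        "rpl16", "sdh3", "sdh4", "atp9",  # second atp9 locus
    ),
)

MITO_TRN_BY_CHROM = (
    ("trnC-GCA", "trnD-GUC", "trnE-UUC"),
    (
        "trnF-GAA", "trnfM-CAU", "trnG-GCC", "trnH-GUG", "trnI-CAU",
        "trnK-UUU", "trnL-CAA",
    ),
    (
        "trnM-CAU", "trnN-GUU", "trnP-UGG", "trnQ-UUG", "trnS-GCU",
        "trnS-UGA", "trnW-CCA", "trnY-GUA", "trnS-GGA", "trnR-ACG",
        "trnR-UCU", "trnT-GGU", "trnV-UAC", "trnL-UAA", "trnG-UCC",
        "trnI-GAU",
    ),
)

MITO_RRN_BY_CHROM = (
    ("rrn18", "rrn5"),
    ("rrn18", "rrn18", "rrn26", "rrn26", "rrn5"),
    ("rrn26", "rrn5", "rrn18"),
)

MITO_CHROMOSOMES = (("mt1", 87933), ("mt2", 303254), ("mt3", 241909))

# region partitions of reference plastomes, used for cross-species
# region-size comparisons (bar-plot style tables)
REFERENCE_PARTITIONS: dict[str, dict[str, int]] = {
    "Lindenbergia_philippensis": {"LSC": 85520, "SSC": 16293, "IR": 24000},
    "Striga_asiatica": {"LSC": 51312, "SSC": 8440, "IR": 63360},
    "Melampyrum_koreanum": {"LSC": 84740, "SSC": 9385, "IR": 24740},
    "Lathraea_squamaria": {"LSC": 85882, "SSC": 14622, "IR": 25000},
    "Christisonia_kwangtungensis": {"LSC": 30072, "SSC": 480, "IR": 32761},
}


def reference_partition(species: str) -> PlastomePartition:
    p = REFERENCE_PARTITIONS[species]
    return PlastomePartition.from_lengths(p["LSC"], p["SSC"], p["IR"])


# ==========================================================================
# fixture spec


@dataclass(frozen=True)
class PlantedTransfer:
    """A plastid-derived fragment to embed in a mitochondrial chromosome."""

    gene: str
    donor: str
    length: int
    chromosome: str
    gene_offset: int = 0
    orf_complete: bool = False


DEFAULT_TRANSFERS = (
    PlantedTransfer("petB", "Lamiales", 201, "mt1", gene_offset=30),
    PlantedTransfer("ycf15", "unknown", 120, "mt1", gene_offset=60),
    PlantedTransfer("rpoB", "Lamiales", 240, "mt2", gene_offset=21),
    PlantedTransfer("ndhB", "Lamiales", 210, "mt2", gene_offset=45),
    PlantedTransfer("ycf2", "Orchidaceae", 420, "mt2", gene_offset=30),
    PlantedTransfer("rpl20", "Lamiales", 195, "mt3", gene_offset=24),
    PlantedTransfer("rpl14", "Gentianaceae", 180, "mt3", gene_offset=33),
    PlantedTransfer("rpl16", "Gentianaceae", 210, "mt3", gene_offset=27),
    PlantedTransfer("ycf2", "unknown", 100, "mt3", gene_offset=600),
)


def default_gene_statuses() -> dict[str, str]:
    statuses = {}
    for g in INTACT_TRN + INTACT_RRN + INTACT_RPS + INTACT_RPL + INTACT_OTHER:
        statuses[g] = "intact"
    for g in PSEUDOGENES:
        statuses[g] = "pseudogene"
    for g in LOST_GENES:
        statuses[g] = "lost"
    return statuses


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture set.

    plastome_regions gives the four region lengths (one IR value, used for
    both copies); gene_statuses maps every reference gene to
    intact/pseudogene/lost; planted_transfers lists the plastid fragments
    embedded in the mitogenome.
    """

    seed: int = 0
    plastome_regions: dict[str, int] = field(
        default_factory=lambda: {"LSC": 30072, "SSC": 480, "IR": 32761}
    )
    gene_statuses: dict[str, str] = field(default_factory=default_gene_statuses)
    planted_transfers: tuple[PlantedTransfer, ...] = DEFAULT_TRANSFERS
    chromosomes: tuple[tuple[str, int], ...] = MITO_CHROMOSOMES
    transfer_mutation_rate: float = 0.0
    ir_genes: tuple[str, ...] = IR_GENES
    ssc_genes: tuple[str, ...] = SSC_GENES
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(LONG_GENES))

    def __post_init__(self):
        for name, length in self.plastome_regions.items():
            if length <= 0:
                raise ValueError(f"region {name} must have positive length")
        valid = {"intact", "pseudogene", "lost"}
        bad = {s for s in self.gene_statuses.values() if s not in valid}
        if bad:
            raise ValueError(f"invalid statuses {bad}")
        overlap = set(self.ir_genes) & set(self.ssc_genes)
        if overlap:
            raise ValueError(
                f"gene(s) {sorted(overlap)} assigned to both IR and SSC"
            )
        for t in self.planted_transfers:
            if t.gene not in self.gene_statuses and t.gene not in PLASTID_REFERENCE_GENES:
                raise ValueError(f"planted transfer gene {t.gene!r} not in donor catalog")
            if not 0.0 <= self.transfer_mutation_rate < 1.0:
                raise ValueError("mutation rate outside [0,1)")

    # -- JSON round trip ---------------------------------------------------

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        doc["planted_transfers"] = [dataclasses.asdict(t) for t in self.planted_transfers]
        doc["chromosomes"] = [list(c) for c in self.chromosomes]
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        doc = json.loads(text)
        doc["planted_transfers"] = tuple(
            PlantedTransfer(**t) for t in doc.get("planted_transfers", [])
        )
        doc["chromosomes"] = tuple(tuple(c) for c in doc.get("chromosomes", []))
        doc["ir_genes"] = tuple(doc.get("ir_genes", IR_GENES))
        doc["ssc_genes"] = tuple(doc.get("ssc_genes", SSC_GENES))
        return cls(**doc)


# ==========================================================================
# sequence generation helpers

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=p)
    return _BASE_CODES[idx].tobytes().decode("ascii")


_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_cds(rng: np.random.Generator, n: int) -> str:
    """Random CDS of n bp (n divisible by 3): ATG + non-stop codons + TAA."""
    ncod = n // 3
    body = rng.choice(_NONSTOP_CODONS, size=max(ncod - 2, 0))
    return ("ATG" + "".join(body) + "TAA")[:n]


def reference_gene_length(name: str, overrides: dict[str, int] | None = None) -> int:
    if overrides and name in overrides:
        return overrides[name]
    cat = categorize(name)
    return GENE_LENGTHS.get(cat, 300)


def make_reference_catalog(
    seed: int = 0,
    genes: tuple[str, ...] = PLASTID_REFERENCE_GENES,
    length_overrides: dict[str, int] | None = None,
) -> dict[str, str]:
    """Reference (non-parasite donor) plastid gene panel: gene -> sequence."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    overrides = dict(LONG_GENES)
    if length_overrides:
        overrides.update(length_overrides)
    out = {}
    for name in genes:
        n = reference_gene_length(name, overrides)
        if is_structural_rna(name):
            out[name] = _random_seq(rng, n, gc=0.42)
        else:
            out[name] = _random_cds(rng, n)
    return out


def _apply_defect(rng: np.random.Generator, seq: str, structural: bool) -> str:
    """Plant a pseudogene defect: internal stop or truncation to 40%."""
    if structural or rng.random() < 0.5:
        return seq[: max(int(0.4 * len(seq)), 12)]
    ncod = len(seq) // 3
    lo, hi = max(int(0.1 * ncod), 1), max(int(0.6 * ncod), 2)
    i = int(rng.integers(lo, hi))
    return seq[: 3 * i] + "TAA" + seq[3 * i + 3 :]


def _mismatch_base(base: str) -> str:
    return "A" if base != "A" else "C"


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
    return "".join(chars)


def _layout_region(
    rng: np.random.Generator,
    region_len: int,
    items: list[tuple[str, str]],  # (name, sequence)
    gc: float,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Place items left to right with uniform random-filler spacers."""
    total = sum(len(s) for _, s in items)
    n = len(items)
    if total + 8 * (n + 1) > region_len:
        raise ValueError(
            f"genes ({total} bp) do not fit in region of {region_len} bp"
        )
    spacer = (region_len - total) // (n + 1) if n else region_len
    parts = []
    coords = []
    pos = 0
    for name, seq in items:
        parts.append(_random_seq(rng, spacer, gc))
        pos += spacer
        coords.append((name, pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
    parts.append(_random_seq(rng, region_len - pos, gc))
    return "".join(parts), coords


def _force_boundary(seq: str) -> str:
    """Pin the first/last four bases to A so that inverted-repeat extension
    cannot creep past a region boundary (A pairs with T, never with the
    complement of A)."""
    if len(seq) < 8:
        return "A" * len(seq)
    return "AAAA" + seq[4:-4] + "AAAA"


# ==========================================================================
# plastome fixture


def make_plastome_fixture(spec: FixtureSpec) -> tuple[str, GeneCatalog]:
    """Circular plastome sequence + annotation for a fixture spec.

    Layout is LSC + IRa + SSC + IRb with IRb the exact reverse complement
    of IRa.  Genes marked pseudogene carry a planted defect; genes marked
    lost have no homologous segment anywhere in the molecule.
    """
    regions = spec.plastome_regions
    lsc_len, ssc_len, ir_len = regions["LSC"], regions["SSC"], regions["IR"]
    reference = make_reference_catalog(spec.seed, length_overrides=spec.gene_lengths)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    present = {
        g: s for g, s in spec.gene_statuses.items() if s in ("intact", "pseudogene")
    }
    unknown = set(present) - set(reference)
    if unknown:
        raise ValueError(f"genes {sorted(unknown)} missing from reference catalog")

    def realized(name: str) -> str:
        seq = reference[name]
        if present[name] == "pseudogene":
            return _apply_defect(rng, seq, is_structural_rna(name))
        return seq

    ir_set = [g for g in spec.ir_genes if g in present]
    ssc_set = [g for g in spec.ssc_genes if g in present]
    lsc_set = [g for g in sorted(present) if g not in ir_set and g not in ssc_set]

    gc = 0.35
    sequences = {g: realized(g) for g in present}
    lsc_seq, lsc_coords = _layout_region(
        rng, lsc_len, [(g, sequences[g]) for g in lsc_set], gc
    )
    ira_seq, ira_coords = _layout_region(
        rng, ir_len, [(g, sequences[g]) for g in ir_set], gc
    )
    ssc_seq, ssc_coords = _layout_region(
        rng, ssc_len, [(g, sequences[g]) for g in ssc_set], gc
    )
    lsc_seq = _force_boundary(lsc_seq)
    ssc_seq = _force_boundary(ssc_seq)
    irb_seq = revcomp(ira_seq)
    genome = lsc_seq + ira_seq + ssc_seq + irb_seq

    rep = "plastome"
    records = []
    for name, s, e in lsc_coords:
        records.append(
            GeneRecord(name, categorize(name), rep, s, e, 1, 1, genome[s:e])
        )
    ira_off = lsc_len
    for name, s, e in ira_coords:
        records.append(
            GeneRecord(
                name, categorize(name), rep, ira_off + s, ira_off + e, 1, 1,
                genome[ira_off + s : ira_off + e],
            )
        )
    ssc_off = lsc_len + ir_len
    for name, s, e in ssc_coords:
        records.append(
            GeneRecord(
                name, categorize(name), rep, ssc_off + s, ssc_off + e, 1, 1,
                genome[ssc_off + s : ssc_off + e],
            )
        )
    # mirrored copies in IRb, on the minus strand
    irb_off = lsc_len + ir_len + ssc_len
    for name, s, e in ira_coords:
        ms, me = irb_off + ir_len - e, irb_off + ir_len - s
        records.append(
            GeneRecord(
                name, categorize(name), rep, ms, me, -1, 2,
                revcomp(genome[ms:me]),
            )
        )
    catalog = GeneCatalog(genes=records, replicon_lengths={rep: len(genome)})
    catalog.validate()
    return genome, catalog


# ==========================================================================
# mitogenome fixture


def make_mitogenome_fixture(
    spec: FixtureSpec,
) -> tuple[dict[str, str], GeneCatalog, pd.DataFrame]:
    """Multi-chromosome mitogenome with local genes and planted transfers.

    Returns (chromosome sequences, local-gene catalog, planted-truth table
    with the exact coordinates of every embedded plastid fragment).
    """
    reference = make_reference_catalog(spec.seed, length_overrides=spec.gene_lengths)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    chrom_names = [c[0] for c in spec.chromosomes]
    chrom_lens = dict(spec.chromosomes)

    for t in spec.planted_transfers:
        if t.chromosome not in chrom_lens:
            raise ValueError(f"unknown chromosome {t.chromosome!r}")
        if t.length > chrom_lens[t.chromosome]:
            raise ValueError(f"fragment {t.gene} longer than {t.chromosome}")
        if t.gene_offset + t.length > len(reference[t.gene]):
            raise ValueError(f"fragment {t.gene} exceeds its reference gene")

    n_chrom = len(chrom_names)
    pcg = MITO_PCG_BY_CHROM[:n_chrom] if n_chrom <= 3 else MITO_PCG_BY_CHROM
    trn = MITO_TRN_BY_CHROM[:n_chrom]
    rrn = MITO_RRN_BY_CHROM[:n_chrom]

    sequences: dict[str, str] = {}
    records: list[GeneRecord] = []
    truth_rows = []
    copy_counter: dict[str, int] = {}
    for ci, name in enumerate(chrom_names):
        length = chrom_lens[name]
        items: list[tuple[str, str, str]] = []  # (kind, label, seq)
        for g in (pcg[ci] if ci < len(pcg) else ()):
            items.append(("gene", g, _random_cds(rng, 300)))
        for g in (trn[ci] if ci < len(trn) else ()):
            items.append(("gene", g, _random_seq(rng, 80, gc=0.44)))
        for g in (rrn[ci] if ci < len(rrn) else ()):
            items.append(("gene", g, _random_seq(rng, 120, gc=0.44)))
        for t in spec.planted_transfers:
            if t.chromosome != name:
                continue
            frag = reference[t.gene][t.gene_offset : t.gene_offset + t.length]
            if t.orf_complete:
                frag = reference[t.gene]
            frag = _mutate(rng, frag, spec.transfer_mutation_rate)
            items.append(("transfer", t.gene, frag))
        seq, coords = _layout_region(
            rng, length, [(lab, s) for _, lab, s in items], gc=0.44
        )
        # Guard the flanks of every planted fragment: pin the four filler
        # bases on each side to differ from the continuation of the donor
        # gene, so homology extension ends exactly at the planted edges.
        chars = list(seq)
        ti = 0
        for (kind, lab, _), (_, s, e) in zip(items, coords):
            if kind != "transfer":
                continue
            t = [x for x in spec.planted_transfers if x.chromosome == name][ti]
            ti += 1
            ref = reference[t.gene]
            off, ln = (0, len(ref)) if t.orf_complete else (t.gene_offset, t.length)
            for d in range(1, 5):
                if s - d >= 0 and off - d >= 0:
                    chars[s - d] = _mismatch_base(ref[off - d])
                j = off + ln + d - 1
                if e + d - 1 < length and j < len(ref):
                    chars[e + d - 1] = _mismatch_base(ref[j])
        seq = "".join(chars)
        sequences[name] = seq
        for (kind, lab, _), (lab2, s, e) in zip(items, coords):
            if kind == "gene":
                copy_counter[lab] = copy_counter.get(lab, 0) + 1
                records.append(
                    GeneRecord(
                        lab, categorize(lab, "mito"), name, s, e, 1,
                        copy_counter[lab], seq[s:e],
                    )
                )
            else:
                truth_rows.append(
                    {"gene": lab, "replicon": name, "start": s, "end": e}
                )

    truth = pd.DataFrame(
        truth_rows, columns=["gene", "replicon", "start", "end"]
    ).sort_values(["replicon", "start"]).reset_index(drop=True)
    counters: dict[str, int] = {}
    copies = []
    for g in truth["gene"]:
        counters[g] = counters.get(g, 0) + 1
        copies.append(counters[g])
    truth["copy"] = copies
    catalog = GeneCatalog(
        genes=records, replicon_lengths={n: len(s) for n, s in sequences.items()}
    )
    catalog.validate()
    return sequences, catalog, truth


# ==========================================================================
# donor-tree scenarios


@dataclass(frozen=True)
class TreeScenario:
    """A named donor-tree topology with bootstrap supports."""

    name: str
    newick: str
    query: str
    groups: dict[str, str]
    outgroup: str
    n_informative_sites: int


def make_tree_fixture(scenario: TreeScenario) -> str:
    """Validated Newick text for a scenario (supports as node labels)."""
    import dendropy

    try:
        tree = dendropy.Tree.get(
            data=scenario.newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate tip labels: {e}") from e
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip labels")
    if tips.count(scenario.query) != 1:
        raise ValueError("query tip must be present exactly once")
    if scenario.outgroup not in tips:
        raise ValueError("designated outgroup absent")
    for node in tree.preorder_internal_node_iter():
        if node.label not in (None, ""):
            v = float(node.label)
            if not 0 <= v <= 100:
                raise ValueError(f"support {v} outside [0,100]")
    return scenario.newick


def _igt_scenario(gene: str, n_sites: int, support: tuple[int, int] = (90, 95)) -> TreeScenario:
    q = f"Ckw_{gene}"
    inner, outer = support
    newick = (
        f"((({q}:0.010,Lamiales_1:0.010){inner}:0.012,Lamiales_2:0.015)"
        f"{outer}:0.020,(Orchidaceae_1:0.030,Orchidaceae_2:0.030)99:0.030,"
        f"Outgroup_1:0.080);"
    )
    groups = {
        "Lamiales_1": "Lamiales",
        "Lamiales_2": "Lamiales",
        "Orchidaceae_1": "Orchidaceae",
        "Orchidaceae_2": "Orchidaceae",
        "Outgroup_1": "outgroup",
    }
    return TreeScenario(f"IGT-{gene}", newick, q, groups, "Outgroup_1", n_sites)


def default_tree_scenarios() -> dict[str, TreeScenario]:
    """Donor-tree scenarios keyed by fragment id (gene-copy)."""
    scenarios: dict[str, TreeScenario] = {
        "rpoB-1": _igt_scenario("rpoB", 24),
        "ndhB-1": _igt_scenario("ndhB", 19),
        "petB-1": _igt_scenario("petB", 17),
        "rpl20-1": _igt_scenario("rpl20", 3),
    }
    q = "Ckw_ycf2"
    scenarios["ycf2-1"] = TreeScenario(
        "HGT-ycf2",
        f"(((({q}:0.010,Bletilla_1:0.010)64:0.010,"
        f"(Orchidaceae_1:0.015,Orchidaceae_2:0.015)90:0.012)85:0.020,"
        f"(Lamiales_1:0.010,Lamiales_2:0.012)95:0.020)92:0.015,"
        f"Gentianaceae_1:0.040,Outgroup_1:0.080);",
        q,
        {
            "Bletilla_1": "Orchidaceae",
            "Orchidaceae_1": "Orchidaceae",
            "Orchidaceae_2": "Orchidaceae",
            "Lamiales_1": "Lamiales",
            "Lamiales_2": "Lamiales",
            "Gentianaceae_1": "Gentianaceae",
            "Outgroup_1": "outgroup",
        },
        "Outgroup_1",
        21,
    )
    for gene, n_sites in (("rpl14", 11), ("rpl16", 14)):
        q = f"Ckw_{gene}"
        scenarios[f"{gene}-1"] = TreeScenario(
            f"HGT-{gene}",
            f"((({q}:0.010,Gentianaceae_1:0.010)100:0.012,"
            f"Gentianaceae_2:0.015)100:0.020,"
            f"(Lamiales_1:0.010,Lamiales_2:0.012)95:0.020,Outgroup_1:0.080);",
            q,
            {
                "Gentianaceae_1": "Gentianaceae",
                "Gentianaceae_2": "Gentianaceae",
                "Lamiales_1": "Lamiales",
                "Lamiales_2": "Lamiales",
                "Outgroup_1": "outgroup",
            },
            "Outgroup_1",
            n_sites,
        )
    for key, gene, n_sites in (("ycf15-1", "ycf15", 2), ("ycf2-2", "ycf2", 1)):
        q = f"Ckw_{key}"
        scenarios[key] = TreeScenario(
            f"short-{key}",
            f"((({q}:0.010,Lamiales_1:0.010)50:0.010,Lamiales_2:0.012)55:0.010,"
            f"(Orchidaceae_1:0.020,Orchidaceae_2:0.020)60:0.020,Outgroup_1:0.080);",
            q,
            {
                "Lamiales_1": "Lamiales",
                "Lamiales_2": "Lamiales",
                "Orchidaceae_1": "Orchidaceae",
                "Orchidaceae_2": "Orchidaceae",
                "Outgroup_1": "outgroup",
            },
            "Outgroup_1",
            n_sites,
        )
    return scenarios


# ==========================================================================
# alignment fixtures for the site audit


def make_rpl20_alignment(seed: int = 0, pivot_column: int = 187) -> dict[str, str]:
    """Alignment whose donor signal rests on one informative column.

    The query shares a G with the Lamiaceae rows at the pivot column
    (1-based); every other taxon carries an A there.  All other columns are
    uninformative, so a single A<->G change at the pivot re-routes the
    donor call -- the single-site fragility situation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    ncol = 240
    base = _random_seq(rng, ncol, gc=0.4)
    rows = {
        "Ckw_rpl20": list(base),
        "Lamiaceae_1": list(base),
        "Lamiaceae_2": list(base),
        "Orobanchaceae_1": list(base),
        "Orobanchaceae_2": list(base),
        "Outgroup_1": list(base),
    }
    j = pivot_column - 1
    for name in rows:
        rows[name][j] = "A"
    for name in ("Ckw_rpl20", "Lamiaceae_1", "Lamiaceae_2"):
        rows[name][j] = "G"
    # scatter singleton substitutions (uninformative by definition)
    others = [n for n in rows if n != "Ckw_rpl20"]
    for col in (10, 40, 85, 130, 200):
        name = others[int(rng.integers(len(others)))]
        old = rows[name][col]
        rows[name][col] = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
    return {n: "".join(chars) for n, chars in rows.items()}


def make_consistent_alignment(
    seed: int = 0, n_support: int = 10
) -> dict[str, str]:
    """Control alignment with n_support concordant informative columns.

    Every informative column places the query with group A, so no single
    site change can re-route the donor call.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    ncol = max(12 * n_support, 60)
    base = _random_seq(rng, ncol, gc=0.4)
    rows = {
        "query": list(base),
        "A_1": list(base),
        "A_2": list(base),
        "B_1": list(base),
        "B_2": list(base),
    }
    cols = np.linspace(5, ncol - 5, n_support).astype(int)
    for j in cols:
        for name in rows:
            rows[name][j] = "A"
        for name in ("query", "A_1", "A_2"):
            rows[name][j] = "G"
    return {n: "".join(chars) for n, chars in rows.items()}


# ==========================================================================
# expression and content-matrix fixtures

_CK_KO00195_DETECTED = (
    "psbA", "psbB", "psbC", "psaA", "psaB", "petB", "petD",
    "atpA", "atpB", "atpC", "atpF",
)
_AI_KO00195_DETECTED = (
    "psbW", "petE", "petF", "atpA", "atpB", "atpC", "atpD",
)
_CK_KO00860_DETECTED = (
    "hemA", "hemL", "hemB", "hemC", "hemD", "hemE", "hemF", "hemN", "hemY",
    "chlH", "chlM", "chlE",
)

_EXPRESSION_SETS = {
    ("Christisonia_kwangtungensis", "ko00195"): _CK_KO00195_DETECTED,
    ("Aeginetia_indica", "ko00195"): _AI_KO00195_DETECTED,
    ("Christisonia_kwangtungensis", "ko00860"): _CK_KO00860_DETECTED,
}


def make_expression_fixture(species: str, pathway_id: str) -> ExpressionEvidence:
    """Detection flags over the full pathway roster for one species."""
    key = (species, pathway_id)
    if key not in _EXPRESSION_SETS:
        raise KeyError(f"no expression fixture for {key}")
    detected = set(_EXPRESSION_SETS[key])
    pathway = load_builtin(pathway_id)
    return ExpressionEvidence(
        species=species,
        detected={g: g in detected for g in sorted(pathway.genes)},
    )


def _species_statuses() -> dict[str, dict[str, str]]:
    all_genes = PLASTID_REFERENCE_GENES
    trn_sorted = sorted(g for g in all_genes if g.startswith("trn"))

    def row(lost=(), pseudo=()):
        out = {}
        for g in all_genes:
            out[g] = (
                "lost" if g in lost else "pseudogene" if g in pseudo else "intact"
            )
        return out

    ck = default_gene_statuses()
    ai_lost = set(LOST_GENES) | {"psbI", "psbD", "petB", "ndhB", "ycf15", "rpl23"}
    ai_pseudo = {
        "rps16", "rpoB", "atpE", "rpoA", "rps15",
        "atpF", "atpH", "clpP", "infA", "matK", "accD",
        "rps2", "rps3", "rps7", "rpl2",
    }
    return {
        "Lindenbergia_philippensis": row(),
        "Striga_asiatica": row(
            lost={"ndhF"},
            pseudo={"ndhA", "ndhB", "ndhD", "ndhG", "ndhH"},
        ),
        "Melampyrum_koreanum": row(
            lost={"ndhA", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH"},
            pseudo={"ndhB", "ndhI", "ndhJ", "ndhK"},
        ),
        "Lathraea_squamaria": row(
            lost={"ndhA", "ndhC", "ndhD", "ndhE", "ndhF"},
            pseudo=(
                {"ndhB", "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK"}
                | {"psaC", "psaI", "psaJ"}
                | {"psbB", "psbE", "psbF", "psbH", "psbJ", "psbK", "psbZ"}
                | {"petG", "petL"}
                | set(trn_sorted[:12])
            ),
        ),
        "Euphrasia_regelii": row(
            lost={"ndhA", "ndhC", "ndhD", "ndhE", "ndhF"},
            pseudo={"ndhB", "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK"},
        ),
        "Aeginetia_indica": row(lost=ai_lost, pseudo=ai_pseudo),
        "Christisonia_kwangtungensis": ck,
    }


def make_content_matrix() -> pd.DataFrame:
    """Species x gene status matrix for the cross-clade comparison.

    Row totals for the hemi/holo pairs encode the published counts (e.g.
    the Rhinantheae hemi-parasite with 7 losses / 4 pseudogenes against
    the clade's holoparasite with 5 losses / 30 pseudogenes); gene
    identities beyond the printed lists are filled arbitrarily but
    consistently.
    """
    statuses = _species_statuses()
    return pd.DataFrame.from_dict(statuses, orient="index")[
        list(PLASTID_REFERENCE_GENES)
    ]


def species_stage_profile(species: str) -> dict[str, tuple[int, int]]:
    """Per-category (intact, total) profile of a content-matrix species."""
    matrix = make_content_matrix()
    if species not in matrix.index:
        raise KeyError(species)
    profile: dict[str, list[int]] = {}
    for gene, status in matrix.loc[species].items():
        cat = categorize(gene)
        profile.setdefault(cat, [0, 0])
        profile[cat][1] += 1
        if status == "intact":
            profile[cat][0] += 1
    return {c: (v[0], v[1]) for c, v in profile.items()}


# ==========================================================================
# fixture-set writer


def write_fixture_set(spec: FixtureSpec, outdir: str | Path) -> dict[str, str]:
    """Generate and write the full fixture set; returns path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    plastome, pl_catalog = make_plastome_fixture(spec)
    write_fasta({"plastome": plastome}, out / "plastome.fasta")
    pl_catalog.write_gff3(out / "plastome.gff3")
    paths["plastome_fasta"] = str(out / "plastome.fasta")
    paths["plastome_gff3"] = str(out / "plastome.gff3")

    reference = make_reference_catalog(spec.seed, length_overrides=spec.gene_lengths)
    write_fasta(reference, out / "plastid_reference_genes.fasta")
    paths["reference_fasta"] = str(out / "plastid_reference_genes.fasta")

    mito, mt_catalog, truth = make_mitogenome_fixture(spec)
    write_fasta(mito, out / "mitogenome.fasta")
    mt_catalog.write_gff3(out / "mitogenome.gff3")
    truth.to_csv(out / "planted_transfers.tsv", sep="\t", index=False)
    paths["mitogenome_fasta"] = str(out / "mitogenome.fasta")
    paths["mitogenome_gff3"] = str(out / "mitogenome.gff3")
    paths["planted_transfers"] = str(out / "planted_transfers.tsv")

    trees = out / "trees"
    trees.mkdir(exist_ok=True)
    group_rows = []
    for frag_id, sc in default_tree_scenarios().items():
        (trees / f"{frag_id}.nwk").write_text(make_tree_fixture(sc) + "\n")
        for tip, grp in sorted(sc.groups.items()):
            group_rows.append({"fragment": frag_id, "tip": tip, "group": grp})
        group_rows.append({"fragment": frag_id, "tip": sc.query, "group": "query"})
    pd.DataFrame(group_rows).to_csv(out / "tree_groups.tsv", sep="\t", index=False)
    paths["trees_dir"] = str(trees)
    paths["tree_groups"] = str(out / "tree_groups.tsv")

    aln = make_rpl20_alignment(spec.seed)
    write_fasta(aln, out / "rpl20_alignment.fasta")
    paths["rpl20_alignment"] = str(out / "rpl20_alignment.fasta")

    for species, pathway_id in (
        ("Christisonia_kwangtungensis", "ko00195"),
        ("Aeginetia_indica", "ko00195"),
        ("Christisonia_kwangtungensis", "ko00860"),
    ):
        ev = make_expression_fixture(species, pathway_id)
        p = out / f"expression_{species}_{pathway_id}.tsv"
        ev.write_tsv(p)
        paths[f"expression_{species}_{pathway_id}"] = str(p)

    make_content_matrix().to_csv(out / "content_matrix.tsv", sep="\t")
    paths["content_matrix"] = str(out / "content_matrix.tsv")

    (out / "fixture_spec.json").write_text(spec.to_json() + "\n")
    paths["spec"] = str(out / "fixture_spec.json")
    return paths
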