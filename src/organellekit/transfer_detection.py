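"""Detection of plastid-derived fragments in mitochondrial chromosomes.

Scans mitochondrial sequences against a reference plastid gene panel with
a seeded ungapped aligner (or ingests precomputed 12-column BLAST tabular
hits), chains nearby same-gene hits into fragments, and assesses whether
each fragment carries a translatable full-length ORF.  Mitochondrial
plastid insertions (MIPTs) in parasites are typically fragmentary; the
ORF-completeness call makes that explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from ._align import evalue as _evalue
from ._align import local_hits, revcomp, translate

DEFAULT_EVALUE_CUTOFF = 1e-10
DEFAULT_JOIN_GAP = 50

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class HomologyHit:
    """A significant local match of a plastid gene in a mitochondrial replicon.

    Intervals are 0-based half-open; subject coordinates are on the forward
    strand of the replicon regardless of hit orientation.
    """

    gene: str
    replicon: str
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: int
    identity: float
    length: int
    evalue: float
    score: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0,1]")
        if self.evalue < 0:
            raise ValueError("negative significance")


@dataclass(frozen=True)
class TransferFragment:
    """A plastid-derived segment resident in a mitochondrial chromosome."""

    gene: str
    copy: int
    replicon: str
    start: int
    end: int
    identity: float
    evalue: float
    orf_complete: bool
    orf_reason: str
    source_call: str | None = None  # filled by the phylogenetic classifier

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("fragment length must be > 0")
        if self.copy < 1:
            raise ValueError("copy index must be >= 1")

    @property
    def fragment_id(self) -> str:
        return f"{self.gene}-{self.copy}"

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_homology(
    mito: dict[str, str],
    plastid_ref: dict[str, str],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    join_gap: int = DEFAULT_JOIN_GAP,
    k: int = 13,
) -> list[HomologyHit]:
    """Significant plastid-gene hits on mitochondrial replicons.

    Same-gene hits on one replicon and strand whose subject intervals lie
    within ``join_gap`` of each other are chained into one maximal hit, as
    a single insertion event is routinely split by post-insertion mutation.
    Output is deterministically ordered by (replicon, start).
    """
    if not plastid_ref:
        raise ValueError("reference gene set is empty")
    from ._align import _extend  # seeded X-drop extension

    index: dict[str, list[tuple[str, int]]] = {}
    for gene in sorted(plastid_ref):
        q = plastid_ref[gene]
        for i in range(len(q) - k + 1):
            index.setdefault(q[i : i + k], []).append((gene, i))

    raw: list[HomologyHit] = []
    for rep in sorted(mito):
        forward = mito[rep]
        n = len(forward)
        for strand, subject in ((1, forward), (-1, revcomp(forward))):
            covered: dict[tuple[str, int], list[tuple[int, int]]] = {}
            for si in range(len(subject) - k + 1):
                for gene, qi in index.get(subject[si : si + k], ()):
                    key = (gene, si - qi)
                    if any(
                        lo <= qi and qi + k <= hi for lo, hi in covered.get(key, ())
                    ):
                        continue
                    query = plastid_ref[gene]
                    qs, qe, ss, se, score, matches = _extend(query, subject, qi, si, k)
                    covered.setdefault(key, []).append((qs, qe))
                    e = _evalue(score, len(query), len(subject))
                    if e >= cutoff:
                        continue
                    lo, hi = (ss, se) if strand == 1 else (n - se, n - ss)
                    raw.append(
                        HomologyHit(
                            gene=gene,
                            replicon=rep,
                            qstart=qs,
                            qend=qe,
                            sstart=lo,
                            send=hi,
                            strand=strand,
                            identity=matches / (qe - qs),
                            length=qe - qs,
                            evalue=e,
                            score=score,
                        )
                    )
    return _chain_hits(raw, join_gap)


def _chain_hits(hits: list[HomologyHit], join_gap: int) -> list[HomologyHit]:
    chained: list[HomologyHit] = []
    keyfn = lambda h: (h.replicon, h.gene, h.strand)
    for key in sorted({keyfn(h) for h in hits}):
        group = sorted((h for h in hits if keyfn(h) == key), key=lambda h: h.sstart)
        cur = group[0]
        for nxt in group[1:]:
            if nxt.sstart - cur.send <= join_gap:
                total = (cur.send - cur.sstart) + (nxt.send - nxt.sstart)
                wid = (
                    cur.identity * (cur.send - cur.sstart)
                    + nxt.identity * (nxt.send - nxt.sstart)
                ) / total
                cur = replace(
                    cur,
                    qstart=min(cur.qstart, nxt.qstart),
                    qend=max(cur.qend, nxt.qend),
                    send=max(cur.send, nxt.send),
                    identity=wid,
                    length=max(cur.send, nxt.send) - cur.sstart,
                    evalue=min(cur.evalue, nxt.evalue),
                    score=cur.score + nxt.score,
                )
            else:
                chained.append(cur)
                cur = nxt
        chained.append(cur)
    chained.sort(key=lambda h: (h.replicon, h.sstart, h.gene))
    return chained


def check_orf_completeness(fragment: str, reference_cds: str) -> tuple[bool, str]:
    """Whether a fragment carries the reference's complete, translatable CDS.

    True iff the fragment contains the full reference span with an intact
    start codon, terminal stop, and no internal in-frame stop.  Returns
    (complete, reason); a non-coding reference yields ``not_applicable``.
    """
    ref = reference_cds.upper()
    if len(ref) % 3 != 0 or not ref.startswith("ATG") or ref[-3:] not in _STOPS:
        return False, "not_applicable"
    for frag in (fragment.upper(), revcomp(fragment.upper())):
        hits = local_hits(ref, frag, k=13, both_strands=False)
        if not hits:
            continue
        h = hits[0]
        if h.qend - h.qstart < 0.9 * len(ref):
            return False, "too_short"
        # full-span check: the fragment must extend over the whole CDS
        s0 = h.sstart - h.qstart
        s1 = s0 + len(ref)
        if s0 < 0 or s1 > len(frag):
            return False, "too_short"
        cds = frag[s0:s1]
        if not cds.startswith("ATG"):
            return False, "no_start"
        if cds[-3:] not in _STOPS:
            return False, "no_stop"
        aa = translate(cds)
        if "*" in aa[:-1]:
            return False, "premature_stop"
        return True, "complete"
    return False, "too_short"


def fragments_from_hits(
    hits: list[HomologyHit],
    mito: dict[str, str],
    plastid_ref: dict[str, str],
    replicon_order: list[str] | None = None,
) -> list[TransferFragment]:
    """Transfer fragments with copy indices and ORF-completeness calls.

    Copy indices distinguish repeated insertions of one gene and are
    assigned in (replicon, subject-coordinate) order.
    """
    order = replicon_order or sorted(mito)
    rank = {rep: i for i, rep in enumerate(order)}
    counters: dict[str, int] = {}
    fragments = []
    for h in sorted(hits, key=lambda h: (rank.get(h.replicon, 1 << 30), h.sstart)):
        counters[h.gene] = counters.get(h.gene, 0) + 1
        frag_seq = mito[h.replicon][h.sstart : h.send]
        complete, reason = check_orf_completeness(frag_seq, plastid_ref[h.gene])
        fragments.append(
            TransferFragment(
                gene=h.gene,
                copy=counters[h.gene],
                replicon=h.replicon,
                start=h.sstart,
                end=h.send,
                identity=h.identity,
                evalue=h.evalue,
                orf_complete=complete,
                orf_reason=reason,
            )
        )
    return fragments


# --------------------------------------------------------------------------
# BLAST tabular interoperability

_OUTFMT6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_outfmt6(path: str | Path) -> list[HomologyHit]:
    """Ingest precomputed hits in 12-column BLAST tabular format."""
    df = pd.read_csv(path, sep="\t", names=_OUTFMT6_COLS, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        sstart, send = int(row.sstart), int(row.send)
        strand = 1 if send >= sstart else -1
        lo, hi = (sstart, send) if strand == 1 else (send, sstart)
        hits.append(
            HomologyHit(
                gene=str(row.qseqid),
                replicon=str(row.sseqid),
                qstart=int(row.qstart) - 1,
                qend=int(row.qend),
                sstart=lo - 1,
                send=hi,
                strand=strand,
                identity=float(row.pident) / 100.0,
                length=int(row.length),
                evalue=float(row.evalue),
                score=float(row.bitscore),
            )
        )
    hits.sort(key=lambda h: (h.replicon, h.sstart, h.gene))
    return hits


def write_outfmt6(hits: list[HomologyHit], path: str | Path) -> None:
    rows = []
    for h in hits:
        sstart, send = (h.sstart + 1, h.send) if h.strand == 1 else (h.send, h.sstart + 1)
        rows.append(
            [
                h.gene, h.replicon, round(100 * h.identity, 2), h.length,
                round(h.length * (1 - h.identity)), 0,
                h.qstart + 1, h.qend, sstart, send,
                f"{h.evalue:.2e}", round(h.score, 1),
            ]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def fragments_table(fragments: list[TransferFragment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": f.gene,
                "copy": f.copy,
                "replicon": f.replicon,
                "start": f.start,
                "end": f.end,
                "length": f.length,
                "identity": round(f.identity, 4),
                "orf_complete": f.orf_complete,
                "orf_reason": f.orf_reason,
                "source_call": f.source_call or "",
            }
            for f in fragments
        ]
    )
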