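"""Seeded ungapped local alignment with Karlin-Altschul significance.

Desk-scale replacement for an external nucleotide search tool: exact k-mer
seeding followed by X-drop ungapped extension, scored +1 match / -2 mismatch.
Significance is the classical ungapped expect value E = K m n exp(-lambda S).
Organelle fragments of interest here are near-identical (>=95% nucleotide
identity), for which ungapped extension is lossless in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import Seq

MATCH = 1
MISMATCH = -2
XDROP = 20
# Karlin-Altschul parameters for the +1/-2 nucleotide scoring system.
KA_LAMBDA = 1.33
KA_K = 0.621


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


@dataclass(frozen=True)
class LocalHit:
    """Ungapped local alignment between a query and a subject sequence.

    Coordinates are 0-based half-open on the forward strand of each
    sequence.  ``strand`` is +1 if the query matches the subject as given,
    -1 if it matches the reverse complement of the subject interval.
    """

    qstart: int
    qend: int
    sstart: int
    send: int
    strand: int
    score: int
    matches: int

    @property
    def length(self) -> int:
        return self.qend - self.qstart

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


def evalue(score: int, m: int, n: int) -> float:
    """Ungapped expect value for a score given query/subject lengths."""
    if m <= 0 or n <= 0:
        return math.inf
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def _extend(query: str, subject: str, qi: int, si: int, k: int):
    """X-drop extension of an exact k-mer seed at (qi, si), both directions."""
    score = k * MATCH
    matches = k
    # right
    best, best_q, best_s, best_m = score, qi + k, si + k, matches
    cur = score
    curm = matches
    q, s = qi + k, si + k
    while q < len(query) and s < len(subject):
        if query[q] == subject[s]:
            cur += MATCH
            curm += 1
        else:
            cur += MISMATCH
        q += 1
        s += 1
        if cur > best:
            best, best_q, best_s, best_m = cur, q, s, curm
        elif best - cur > XDROP:
            break
    score, matches = best, best_m
    qend, send = best_q, best_s
    # left
    best, best_q, best_s, best_m = score, qi, si, matches
    cur = score
    curm = matches
    q, s = qi, si
    while q > 0 and s > 0:
        q -= 1
        s -= 1
        if query[q] == subject[s]:
            cur += MATCH
            curm += 1
        else:
            cur += MISMATCH
        if cur > best:
            best, best_q, best_s, best_m = cur, q, s, curm
        elif best - cur > XDROP:
            break
    return best_q, qend, best_s, send, best, best_m


def _kmer_index(seq: str, k: int) -> dict:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _scan_strand(query: str, subject: str, index: dict, k: int) -> list:
    """All distinct ungapped extensions of shared k-mer seeds (one strand)."""
    hits = []
    covered: dict[int, list[tuple[int, int]]] = {}
    for si in range(len(subject) - k + 1):
        kmer = subject[si : si + k]
        for qi in index.get(kmer, ()):  # seeds
            diag = si - qi
            skip = False
            for lo, hi in covered.get(diag, ()):  # already inside an extension
                if lo <= qi and qi + k <= hi:
                    skip = True
                    break
            if skip:
                continue
            qs, qe, ss, se, score, matches = _extend(query, subject, qi, si, k)
            covered.setdefault(diag, []).append((qs, qe))
            hits.append((qs, qe, ss, se, score, matches))
    return hits


def local_hits(
    query: str,
    subject: str,
    k: int = 13,
    both_strands: bool = True,
    min_score: int = 0,
) -> list[LocalHit]:
    """All seeded ungapped local alignments of query against subject.

    Reverse-strand hits are reported with subject coordinates on the forward
    strand of ``subject``.
    """
    if len(query) < k or len(subject) < k:
        return []
    index = _kmer_index(query, k)
    out = []
    for qs, qe, ss, se, score, matches in _scan_strand(query, subject, index, k):
        if score >= min_score:
            out.append(LocalHit(qs, qe, ss, se, +1, score, matches))
    if both_strands:
        rc = revcomp(subject)
        n = len(subject)
        for qs, qe, ss, se, score, matches in _scan_strand(query, rc, index, k):
            if score >= min_score:
                out.append(LocalHit(qs, qe, n - se, n - ss, -1, score, matches))
    out.sort(key=lambda h: (-h.score, h.sstart, h.qstart))
    return out


def best_local_hit(
    query: str, subject: str, k: int = 13, both_strands: bool = True
) -> LocalHit | None:
    hits = local_hits(query, subject, k=k, both_strands=both_strands)
    return hits[0] if hits else None
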