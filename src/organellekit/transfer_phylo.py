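"""Phylogenetic classification of transferred fragments and site audits.

Each plastid-derived fragment found in a mitogenome is placed in a
bootstrap-annotated donor phylogeny and classified as intracellular gene
transfer (IGT: the fragment nests among the parasite's own lineage,
Lamiales / Orobanchaceae), horizontal gene transfer (HGT: the native
lineage is monophyletic without the fragment, which nests in another
family), or undetermined (insufficient support or too few informative
sites).  A site audit asks whether a donor call hinges on a single
parsimony-informative alignment column -- short fragments can be re-routed
between candidate donors by one substitution, so such calls are flagged
fragile rather than trusted.

A small neighbor-joining + bootstrap builder is included so fixture trees
can be produced end to end; it is not a substitute for likelihood-based
tree inference on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

DEFAULT_MIN_SUPPORT = 70.0
DEFAULT_MIN_SITES = 3

#: Groups counted as the parasite's own lineage for the IGT/HGT decision.
NATIVE_GROUPS = frozenset({"Lamiales", "Orobanchaceae"})
OUTGROUP_LABEL = "outgroup"


class TreeError(ValueError):
    pass


@dataclass
class SupportTree:
    """Rooted phylogeny with per-clade bootstrap support and group labels.

    ``groups`` maps every non-query tip to a taxonomic group (family/order
    or ``outgroup``); ``query`` names the transferred-fragment tip.
    Support values live on internal nodes, in percent.
    """

    tree: dendropy.Tree
    groups: dict[str, str]
    query: str
    outgroup: str | None = None
    _support: dict[frozenset, float | None] = field(default_factory=dict, repr=False)

    @classmethod
    def from_newick(
        cls,
        newick: str,
        groups: dict[str, str],
        query: str,
        outgroup: str | None = None,
    ) -> "SupportTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) != len(set(tips)):
            raise TreeError("duplicate tip labels")
        if query not in tips:
            raise TreeError(f"query tip {query!r} absent")
        missing = [t for t in tips if t != query and t not in groups]
        if missing:
            raise TreeError(f"group map incomplete: {missing}")
        if outgroup is None:
            outgroup = next(
                (t for t in tips if groups.get(t) == OUTGROUP_LABEL), None
            )
            if outgroup is None:
                raise TreeError("no outgroup designated and none mapped")
        if outgroup not in tips:
            raise TreeError(f"outgroup {outgroup!r} absent")

        # Collect clade supports as bipartitions keyed by the side away
        # from the outgroup; this makes them stable under rerooting.
        support: dict[frozenset, float | None] = {}
        all_tips = frozenset(tips)
        for node in tree.preorder_internal_node_iter():
            leafset = frozenset(l.taxon.label for l in node.leaf_iter())
            if leafset == all_tips:
                continue
            val = None
            if node.label not in (None, ""):
                val = float(node.label)
                if not 0.0 <= val <= 100.0:
                    raise TreeError(f"support {val} outside [0,100]")
            key = leafset if outgroup not in leafset else all_tips - leafset
            if key and support.get(key) is None:
                support[key] = val

        # Root on the outgroup edge so clade queries are well defined.
        og_node = tree.find_node_with_taxon_label(outgroup)
        tree.reroot_at_edge(og_node.edge, update_bipartitions=False)
        st = cls(tree=tree, groups=dict(groups), query=query, outgroup=outgroup)
        st._support = support
        return st

    # -- queries -----------------------------------------------------------

    @property
    def tips(self) -> set[str]:
        return {l.taxon.label for l in self.tree.leaf_node_iter()}

    def tips_in_groups(self, wanted: frozenset | set) -> set[str]:
        return {t for t, g in self.groups.items() if g in wanted and t in self.tips}

    def clade_support(self, tip_set: frozenset) -> float | None:
        return self._support.get(frozenset(tip_set))

    def _leafset(self, node) -> frozenset:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def is_monophyletic(self, tip_set) -> tuple[bool, float | None]:
        """Whether tip_set is exactly the descendant set of some clade.

        Returns (True, support of that clade) or (False, None).  Checked on
        the tree rooted at the outgroup.
        """
        tip_set = frozenset(tip_set)
        if not tip_set:
            raise TreeError("empty tip set")
        unknown = tip_set - self.tips
        if unknown:
            raise TreeError(f"unknown tips {sorted(unknown)}")
        if len(tip_set) == 1:
            return True, None  # a single tip is trivially a clade
        for node in self.tree.preorder_internal_node_iter():
            if self._leafset(node) == tip_set:
                return True, self.clade_support(tip_set)
        return False, None

    def enclosing_supported_clade(
        self, min_support: float
    ) -> tuple[frozenset, float] | None:
        """Smallest clade containing the query with support >= min_support.

        Nodes without a recorded support (hidden low values) are treated as
        unsupported.  Returns (descendant tip set, support) or None when no
        supported clade short of the whole ingroup exists.
        """
        node = self.tree.find_node_with_taxon_label(self.query)
        all_tips = frozenset(self.tips)
        node = node.parent_node
        while node is not None:
            leafset = self._leafset(node)
            if leafset == all_tips:
                break
            sup = self.clade_support(leafset)
            if sup is not None and sup >= min_support:
                return leafset, sup
            node = node.parent_node
        return None


@dataclass(frozen=True)
class TransferCall:
    """IGT / HGT / undetermined verdict for one transferred fragment."""

    verdict: str  # IGT | HGT | undetermined
    donor: str | None
    support: float | None
    reason: str

    def __post_init__(self):
        if self.verdict == "HGT" and (self.donor is None or self.donor in NATIVE_GROUPS):
            raise ValueError("HGT requires a non-native donor")
        if self.verdict == "IGT" and self.donor not in NATIVE_GROUPS:
            raise ValueError("IGT donor must be the native lineage")
        if self.verdict == "undetermined" and self.donor is not None:
            raise ValueError("undetermined carries no donor")


def classify_transfer(
    tree: SupportTree,
    min_support: float = DEFAULT_MIN_SUPPORT,
    min_sites: int = DEFAULT_MIN_SITES,
    n_informative_sites: int | None = None,
) -> TransferCall:
    """Classify a fragment as IGT, HGT or undetermined.

    IGT: the smallest supported clade containing the query consists (query
    aside) only of Lamiales/Orobanchaceae tips, and the native lineage plus
    the query is monophyletic at >= min_support.  HGT: the native lineage
    without the query is monophyletic at >= min_support and the query's
    smallest supported enclosing clade lies within one other (non-outgroup)
    group, which is reported as the donor.  Everything else -- including
    fragments with fewer informative sites than ``min_sites`` -- is
    undetermined.
    """
    if n_informative_sites is not None and n_informative_sites < min_sites:
        return TransferCall("undetermined", None, None, "too_short")

    native = tree.tips_in_groups(NATIVE_GROUPS)
    enclosing = tree.enclosing_supported_clade(min_support)
    if enclosing is None:
        return TransferCall("undetermined", None, None, "low_support")
    leafset, sup = enclosing
    others = set(leafset) - {tree.query}
    if not others:
        return TransferCall("undetermined", None, None, "low_support")
    other_groups = {tree.groups[t] for t in others}

    if other_groups <= NATIVE_GROUPS:
        mono, msup = tree.is_monophyletic(native | {tree.query})
        if mono and msup is not None and msup >= min_support:
            donor = "Orobanchaceae" if other_groups == {"Orobanchaceae"} else "Lamiales"
            return TransferCall("IGT", donor, msup, "nested_in_Lamiales")
        return TransferCall("undetermined", None, None, "low_support")

    if len(other_groups) == 1:
        donor = next(iter(other_groups))
        if donor != OUTGROUP_LABEL:
            mono, msup = tree.is_monophyletic(native)
            if mono and (msup is not None and msup >= min_support or len(native) == 1):
                return TransferCall("HGT", donor, sup, "nested_in_other_group")
    return TransferCall("undetermined", None, None, "low_support")


# --------------------------------------------------------------------------
# single-site fragility audit


@dataclass(frozen=True)
class SiteAudit:
    """Sensitivity of a two-donor comparison to single-site changes.

    ``support_a`` / ``support_b`` count parsimony-informative columns where
    the query shares its base exclusively with group A resp. group B;
    ``pivotal`` lists 1-based columns where flipping the query base changes
    which grouping wins, with the (current, flipped) bases.
    """

    support_a: int
    support_b: int
    informative: int
    fragile: bool
    pivotal: tuple[tuple[int, str, str], ...]

    @property
    def winner(self) -> str | None:
        if self.support_a > self.support_b:
            return "A"
        if self.support_b > self.support_a:
            return "B"
        return None


def _is_informative(column: list[str]) -> bool:
    counts: dict[str, int] = {}
    for c in column:
        if c in "ACGT":
            counts[c] = counts.get(c, 0) + 1
    return sum(1 for v in counts.values() if v >= 2) >= 2


def _column_vote(qbase: str, a_bases: list[str], b_bases: list[str]) -> str | None:
    """Which group the query base sides with, exclusively, at one column."""
    if qbase not in "ACGT":
        return None
    in_a = qbase in a_bases
    in_b = qbase in b_bases
    if in_a and not in_b:
        return "A"
    if in_b and not in_a:
        return "B"
    return None


def audit_sites(
    alignment: dict[str, str],
    query: str,
    group_a: set[str],
    group_b: set[str],
) -> SiteAudit:
    """Audit which alignment columns decide between two candidate donors.

    Counts informative columns siding with each group, then flips the query
    base at every decisive column (to the other group's base) and checks
    whether any single flip changes the winning group.
    """
    if query not in alignment:
        raise ValueError(f"query row {query!r} absent")
    if group_a & group_b:
        raise ValueError("candidate groups overlap")
    rows = set(alignment)
    for g in group_a | group_b:
        if g not in rows:
            raise ValueError(f"row {g!r} absent from alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    (ncol,) = lengths

    qseq = alignment[query].upper()
    a_rows = [alignment[t].upper() for t in sorted(group_a)]
    b_rows = [alignment[t].upper() for t in sorted(group_b)]
    all_rows = [alignment[t].upper() for t in sorted(alignment)]

    votes: list[str | None] = []
    for j in range(ncol):
        col = [r[j] for r in all_rows]
        if not _is_informative(col):
            votes.append(None)
            continue
        votes.append(
            _column_vote(qseq[j], [r[j] for r in a_rows], [r[j] for r in b_rows])
        )

    support_a = votes.count("A")
    support_b = votes.count("B")
    informative = sum(
        1 for j in range(ncol) if _is_informative([r[j] for r in all_rows])
    )

    def winner(na: int, nb: int) -> str | None:
        return "A" if na > nb else "B" if nb > na else None

    base_winner = winner(support_a, support_b)
    pivotal = []
    for j in range(ncol):
        if votes[j] is None:
            continue
        # flip the query base to each alternative seen in the other rows
        alternatives = sorted(
            {r[j] for r in a_rows + b_rows if r[j] in "ACGT"} - {qseq[j]}
        )
        for alt in alternatives:
            new_vote = _column_vote(alt, [r[j] for r in a_rows], [r[j] for r in b_rows])
            na = support_a - (votes[j] == "A") + (new_vote == "A")
            nb = support_b - (votes[j] == "B") + (new_vote == "B")
            if winner(na, nb) != base_winner:
                pivotal.append((j + 1, qseq[j], alt))
                break
    return SiteAudit(
        support_a=support_a,
        support_b=support_b,
        informative=informative,
        fragile=bool(pivotal),
        pivotal=tuple(pivotal),
    )


def count_informative_sites(alignment: dict[str, str]) -> int:
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    rows = [s.upper() for s in alignment.values()]
    (ncol,) = lengths
    return sum(1 for j in range(ncol) if _is_informative([r[j] for r in rows]))


# --------------------------------------------------------------------------
# neighbor-joining + bootstrap fixture builder


def _p_distance(a: str, b: str) -> float:
    pairs = [
        (x, y) for x, y in zip(a.upper(), b.upper()) if x in "ACGT" and y in "ACGT"
    ]
    if not pairs:
        return 0.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def _nj_from_alignment(alignment: dict[str, str]) -> dendropy.Tree:
    """Neighbor joining on p-distances with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lowest (row, column) index in
    sorted-label order, so identical input always yields an identical tree.
    """
    labels = sorted(alignment)
    if len(labels) < 4:
        raise ValueError("need >= 4 sequences")
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels")
    for lab in labels:
        if not any(c in "ACGT" for c in alignment[lab].upper()):
            raise ValueError(f"all-gap row {lab!r}")

    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _p_distance(alignment[labels[i]], alignment[labels[j]])

    active = list(range(n))
    newick = {i: labels[i] for i in range(n)}
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }

    def dget(i, j):
        return dist[(i, j)] if i < j else dist[(j, i)]

    next_id = n
    while len(active) > 2:
        m = len(active)
        r = {i: sum(dget(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dget(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = dget(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2)) if m > 2 else 0.5 * dij
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        newick[u] = f"({newick[i]}:{li:.10f},{newick[j]}:{lj:.10f})"
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, u), max(k, u))] = 0.5 * (dget(i, k) + dget(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]
    i, j = active
    dij = dget(i, j)
    text = f"({newick[i]}:{dij / 2:.10f},{newick[j]}:{dij / 2:.10f});"
    return dendropy.Tree.get(
        data=text, schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )


def build_nj_tree(alignment: dict[str, str]) -> dendropy.Tree:
    """Neighbor-joining tree on p-distances (fixture plumbing)."""
    return _nj_from_alignment(alignment)


def _bipartitions(tree: dendropy.Tree, ref_label: str, all_labels: frozenset):
    """Non-trivial splits, each keyed by the side away from ref_label."""
    splits = set()
    for node in tree.preorder_internal_node_iter():
        leafset = frozenset(l.taxon.label for l in node.leaf_iter())
        side = leafset if ref_label not in leafset else all_labels - leafset
        if 2 <= len(side) <= len(all_labels) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    alignment: dict[str, str], replicates: int = 100, seed: int = 0
) -> dendropy.Tree:
    """NJ tree with internal-node labels set to bootstrap percentages.

    Columns are resampled with replacement ``replicates`` times; each
    clade's support is the percentage of replicate trees containing the
    same (unrooted) split.  Seeded and reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    labels = sorted(alignment)
    all_labels = frozenset(labels)
    ref = labels[0]
    base = _nj_from_alignment(alignment)
    ncol = len(next(iter(alignment.values())))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = {
            lab: "".join(alignment[lab][j] for j in cols) for lab in labels
        }
        for split in _bipartitions(_nj_from_alignment(resampled), ref, all_labels):
            counts[split] = counts.get(split, 0) + 1
    for node in base.preorder_internal_node_iter():
        leafset = frozenset(l.taxon.label for l in node.leaf_iter())
        side = leafset if ref not in leafset else all_labels - leafset
        if 2 <= len(side) <= len(all_labels) - 2:
            node.label = str(round(100.0 * counts.get(side, 0) / replicates))
    return base
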