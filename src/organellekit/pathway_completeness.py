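"""Pathway-completeness reporting from expression evidence.

Maps per-gene expression detection flags onto pathway component gene sets
(photosynthesis, ko00195) and onto an ordered enzymatic chain (porphyrin /
chlorophyll metabolism, ko00860), counting detected genes per component
and locating the first broken step of a linear chain.

Detection is a boolean supplied by the caller; no expression quantities
are modeled.  Pathway definitions are editable JSON documents shipped with
the package; they freeze one gene roster per pathway and an alias table
for symbol variants (e.g. F-type ATPase subunit names).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class ChainStep:
    """One enzymatic step of a linear chain: EC number, genes, product."""

    enzyme: str
    genes: frozenset[str]
    product: str

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"step {self.enzyme} maps to no gene")


@dataclass
class PathwayDefinition:
    """Component gene sets (and optionally an ordered chain) of a pathway."""

    pathway_id: str
    components: list[tuple[str, dict[str, str]]]  # (name, gene -> compartment)
    chain: list[ChainStep] = field(default_factory=list)
    chain_input: str = ""
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for name, genes in self.components:
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"gene(s) {sorted(overlap)} in multiple components")
            seen |= set(genes)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for _, gset in self.components:
            out |= set(gset)
        return out

    def compartment_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, gset in self.components:
            for comp in gset.values():
                counts[comp] = counts.get(comp, 0) + 1
        return counts

    def resolve(self, symbol: str) -> str:
        return self.aliases.get(symbol, symbol)

    # -- JSON round trip ---------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayDefinition":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_dict(cls, doc: dict) -> "PathwayDefinition":
        return cls(
            pathway_id=doc["pathway_id"],
            components=[(c["name"], dict(c["genes"])) for c in doc["components"]],
            chain=[
                ChainStep(s["enzyme"], frozenset(s["genes"]), s["product"])
                for s in doc.get("chain", [])
            ],
            chain_input=doc.get("chain_input", ""),
            aliases=dict(doc.get("aliases", {})),
        )

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "components": [
                {"name": n, "genes": dict(sorted(g.items()))}
                for n, g in self.components
            ],
            "chain": [
                {"enzyme": s.enzyme, "genes": sorted(s.genes), "product": s.product}
                for s in self.chain
            ],
            "chain_input": self.chain_input,
            "aliases": dict(sorted(self.aliases.items())),
        }


def load_builtin(pathway_id: str) -> PathwayDefinition:
    """Shipped pathway definition (``ko00195`` or ``ko00860``)."""
    text = (
        resources.files("organellekit").joinpath(f"data/{pathway_id}.json").read_text()
    )
    return PathwayDefinition.from_dict(json.loads(text))


@dataclass
class ExpressionEvidence:
    """Per-gene expression detection flags for one species."""

    species: str
    detected: dict[str, bool]

    def detected_set(self) -> set[str]:
        return {g for g, d in self.detected.items() if d}

    @classmethod
    def read_tsv(cls, path: str | Path, species: str = "") -> "ExpressionEvidence":
        df = pd.read_csv(path, sep="\t")
        if df["gene"].duplicated().any():
            raise ValueError("duplicate gene symbols in evidence")
        return cls(
            species=species or str(Path(path).stem),
            detected={
                str(g): bool(d) for g, d in zip(df["gene"], df["detected"])
            },
        )

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.detected.items()), columns=["gene", "detected"]
        ).to_csv(path, sep="\t", index=False)


def map_expression(
    pathway: PathwayDefinition, evidence: ExpressionEvidence
) -> dict:
    """Detected-gene counts per pathway component.

    Evidence genes that are not pathway members are reported under
    ``unmapped`` rather than silently dropped; the conservation invariant
    total_detected == sum(component counts) + unmapped count holds.
    """
    if not evidence.detected:
        raise ValueError("evidence is empty")
    detected = {pathway.resolve(g) for g in evidence.detected_set()}
    per_component = {}
    genes_per_component = {}
    mapped: set[str] = set()
    for name, gset in pathway.components:
        found = sorted(detected & set(gset))
        per_component[name] = len(found)
        genes_per_component[name] = found
        mapped |= set(found)
    unmapped = sorted(detected - mapped)
    return {
        "pathway_id": pathway.pathway_id,
        "species": evidence.species,
        "per_component": per_component,
        "detected_genes": genes_per_component,
        "total_detected": sum(per_component.values()),
        "unmapped": unmapped,
        "pathway_size": len(pathway.genes),
    }


def find_chain_break(
    chain: list[ChainStep] | PathwayDefinition,
    evidence: ExpressionEvidence,
    chain_input: str | None = None,
) -> dict:
    """First undetected step of an ordered enzymatic chain.

    Returns the earliest step with no detected gene and the product of the
    preceding step (the chain input when the first step is broken); when
    every step has a detected gene the chain is complete.
    """
    if isinstance(chain, PathwayDefinition):
        if chain_input is None:
            chain_input = chain.chain_input
        resolver = chain.resolve
        chain = chain.chain
    else:
        resolver = lambda g: g
    if not chain:
        raise ValueError("empty chain")
    detected = {resolver(g) for g in evidence.detected_set()}
    last_product = chain_input or ""
    for i, step in enumerate(chain):
        if not (step.genes & detected):
            return {
                "complete": False,
                "break_step": i + 1,
                "break_enzyme": step.enzyme,
                "last_product": last_product,
            }
        last_product = step.product
    return {
        "complete": True,
        "break_step": None,
        "break_enzyme": None,
        "last_product": last_product,
    }


def report_table(report: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component": name,
                "detected": n,
                "genes": ",".join(report["detected_genes"][name]),
            }
            for name, n in report["per_component"].items()
        ]
    )
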