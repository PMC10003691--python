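"""Cross-link chemistries, distance budgets, and mapping onto assemblies.

A chemical cross-linker covalently tethers two Lys side chains; an
identified cross-linked peptide pair therefore implies an upper bound on
the Calpha-Calpha distance of the two residues:

    budget = spacer + 2 x side-chain allowance + dynamics allowance

With the side-chain allowance of 5.5 A per Lys and a 7.6 A backbone-dynamics
allowance, the CDI linker (spacer 2.6 A) yields a 21.2 A budget and DSBU
(spacer 12.5 A) a 31.1 A budget.  On homo-oligomeric assemblies a link is
ambiguous across symmetry copies; mapping enumerates every cross-copy
candidate pair and takes the minimum distance, and a link is *satisfied*
when that minimum is within (<=) the budget.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .structio import Assembly

__all__ = [
    "LinkerChemistry",
    "CrossLink",
    "XLMapping",
    "SatisfactionReport",
    "CDI",
    "DSBU",
    "DEFAULT_REGISTRY",
    "distance_budget",
    "read_crosslink_table",
    "write_crosslink_table",
    "map_crosslinks",
    "evaluate_satisfaction",
    "write_satisfaction_report",
    "SchemaError",
    "RowError",
    "ConfigurationError",
]


class SchemaError(ValueError):
    """Cross-link table is missing a required column."""


class RowError(ValueError):
    """A table row violates a cross-link invariant; carries provenance."""


class ConfigurationError(ValueError):
    """Protein names cannot be resolved to assembly chains."""


@dataclass(frozen=True)
class LinkerChemistry:
    """A cross-linker and the allowances that define its distance budget.

    All lengths in Angstrom.  ``reactive_targets`` lists the residue types
    the chemistry can modify (protein N-termini are modelled, when enabled,
    as residue 1 of a chain).
    """

    name: str
    spacer_length: float
    sidechain_allowance: float = 5.5
    dynamics_allowance: float = 7.6
    reactive_targets: frozenset[str] = frozenset({"LYS"})

    def __post_init__(self):
        for attr in ("spacer_length", "sidechain_allowance", "dynamics_allowance"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")

    @property
    def budget(self) -> float:
        return self.spacer_length + 2.0 * self.sidechain_allowance + self.dynamics_allowance


CDI = LinkerChemistry("CDI", spacer_length=2.6)
DSBU = LinkerChemistry("DSBU", spacer_length=12.5)
DEFAULT_REGISTRY: dict[str, LinkerChemistry] = {c.name: c for c in (CDI, DSBU)}


def distance_budget(chem: LinkerChemistry) -> float:
    """Maximum Calpha-Calpha distance compatible with a link by *chem* (A)."""
    return chem.budget


@dataclass(frozen=True)
class CrossLink:
    """One identified residue-residue cross-link (author numbering)."""

    protein_a: str
    res_a: int
    protein_b: str
    res_b: int
    linker: str
    score: float | None = None
    source_row: str = ""

    def __post_init__(self):
        if self.res_a < 1 or self.res_b < 1:
            raise RowError(f"{self.source_row or self}: residue numbers must be >= 1")


@dataclass
class XLMapping:
    """A cross-link mapped onto an assembly, ambiguity resolved by minimum."""

    crosslink: CrossLink
    candidate_pairs: list[tuple[str, str, float]]
    min_distance: float
    budget: float
    mappable: bool
    satisfied: bool


@dataclass
class SatisfactionReport:
    n_total: int
    n_mappable: int
    n_satisfied: int
    mappings: list[XLMapping] = field(default_factory=list)


_REQUIRED_COLUMNS = ("protein_a", "res_a", "protein_b", "res_b", "linker")


def read_crosslink_table(path, dialect: str = "auto") -> list[CrossLink]:
    """Read a delimited cross-link identification table.

    Requires a header with columns protein_a, res_a, protein_b, res_b,
    linker (optional: score); comma or tab is sniffed when dialect="auto".
    """
    sep = {"auto": None, "csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None and dialect != "auto":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    links: list[CrossLink] = []
    for i, row in df.iterrows():
        prov = f"{Path(path).name}:row{i + 2}"
        try:
            ra, rb = int(row["res_a"]), int(row["res_b"])
        except (TypeError, ValueError) as exc:
            raise RowError(f"{prov}: unparseable residue number "
                           f"({row['res_a']!r}, {row['res_b']!r})") from exc
        score = None
        if "score" in df.columns and pd.notna(row.get("score")):
            score = float(row["score"])
        links.append(CrossLink(str(row["protein_a"]).strip(), ra,
                               str(row["protein_b"]).strip(), rb,
                               str(row["linker"]).strip(), score, prov))
    return links


def write_crosslink_table(links: Sequence[CrossLink], path) -> None:
    df = pd.DataFrame(
        [{"protein_a": l.protein_a, "res_a": l.res_a, "protein_b": l.protein_b,
          "res_b": l.res_b, "linker": l.linker, "score": l.score} for l in links]
    )
    df.to_csv(path, sep="\t", index=False)


def _resolve_chains(assembly: Assembly, requested: Sequence[str] | None, protein: str) -> list[str]:
    labels = assembly.chain_labels
    if requested is None:
        return labels
    resolved: list[str] = []
    for want in requested:
        hits = [lb for lb in labels if lb == want or lb.split(".", 1)[-1] == want]
        if not hits:
            raise ConfigurationError(
                f"protein {protein!r}: chain {want!r} not found in assembly (have {labels})")
        resolved.extend(hits)
    # preserve flat assembly order, drop duplicates
    seen = set()
    return [lb for lb in labels if lb in set(resolved) and not (lb in seen or seen.add(lb))]


def map_crosslinks(
    assembly: Assembly,
    links: Sequence[CrossLink],
    chain_assignment: Mapping[str, Sequence[str] | None],
    offsets: Mapping[str, int] | None = None,
    registry: Mapping[str, LinkerChemistry] = DEFAULT_REGISTRY,
) -> list[XLMapping]:
    """Map each link onto the assembly, enumerating cross-copy candidates.

    *chain_assignment* maps each protein name to the chain labels (full
    ``copy.chain`` labels or bare chain ids) representing it; ``None`` means
    all chains.  *offsets* shifts link numbering onto model numbering
    (``model_seq = link_res + offset``), making any mismatch between
    precursor-sequence numbering and deposited-model numbering explicit.

    A link whose residue is absent from the model (or has no Calpha) is
    reported with ``mappable=False``.  Candidate pairs never pair a residue
    with itself in the same copy, so a self-link on a homo-oligomer measures
    the inter-copy separation.
    """
    offsets = offsets or {}
    mappings: list[XLMapping] = []
    for link in links:
        if link.linker not in registry:
            raise ConfigurationError(f"linker {link.linker!r} not registered")
        budget = registry[link.linker].budget
        for prot in (link.protein_a, link.protein_b):
            if prot not in chain_assignment:
                raise ConfigurationError(f"no chain assignment for protein {prot!r}")
        chains_a = _resolve_chains(assembly, chain_assignment[link.protein_a], link.protein_a)
        chains_b = _resolve_chains(assembly, chain_assignment[link.protein_b], link.protein_b)
        seq_a = link.res_a + offsets.get(link.protein_a, 0)
        seq_b = link.res_b + offsets.get(link.protein_b, 0)
        pairs: list[tuple[str, str, float]] = []
        for la in chains_a:
            ca_a = assembly.ca_coord(la, seq_a)
            if ca_a is None:
                continue
            for lb in chains_b:
                if la == lb and seq_a == seq_b:
                    continue  # a residue cannot cross-link to itself
                ca_b = assembly.ca_coord(lb, seq_b)
                if ca_b is None:
                    continue
                d = float(math.dist(ca_a, ca_b))
                pairs.append((la, lb, d))
        mappable = bool(pairs)
        min_d = min((p[2] for p in pairs), default=math.inf)
        mappings.append(XLMapping(link, pairs, min_d, budget, mappable,
                                  mappable and min_d <= budget))
    return mappings


def evaluate_satisfaction(mappings: Sequence[XLMapping],
                          count_unmappable: bool = False) -> SatisfactionReport:
    """Tally satisfied links; unmappable links are excluded from the
    denominator unless *count_unmappable* (they are always listed)."""
    n_total = len(mappings)
    n_mappable = sum(m.mappable for m in mappings)
    n_satisfied = sum(m.satisfied for m in mappings)
    if count_unmappable:
        n_mappable = n_total
    return SatisfactionReport(n_total, n_mappable, n_satisfied, list(mappings))


def satisfaction_frame(report: SatisfactionReport) -> pd.DataFrame:
    rows = []
    for m in report.mappings:
        l = m.crosslink
        rows.append({
            "protein_a": l.protein_a, "res_a": l.res_a,
            "protein_b": l.protein_b, "res_b": l.res_b, "linker": l.linker,
            "n_candidates": len(m.candidate_pairs),
            "candidates": ";".join(f"{a}-{b}:{d:.3f}" for a, b, d in m.candidate_pairs),
            "min_distance_A": m.min_distance if m.mappable else float("nan"),
            "budget_A": m.budget,
            "mappable": m.mappable,
            "satisfied": m.satisfied,
        })
    return pd.DataFrame(rows)


def write_satisfaction_report(report: SatisfactionReport, path) -> None:
    satisfaction_frame(report).to_csv(path, sep="\t", index=False)
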