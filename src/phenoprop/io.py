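"""Readers, writers and evidence filters for the pipeline's tabular formats.

All tables are UTF-8 tab-delimited with a header row. The edge list is
(gene_a, gene_b, weight[, source]); the gene–trait evidence table is
(gene, trait_id, trait_class, source, score); organ annotations are
(trait_id, organ); gene sets use the standard GMT dialect.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .exceptions import InputError, ParseError
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

ORGAN_PHENOTYPES = ("retinal", "hearing", "CNS", "polydactyly", "renal", "skeletal")

__all__ = [
    "ORGAN_PHENOTYPES",
    "GeneTraitEvidence",
    "TraitSeedSet",
    "load_network",
    "write_network",
    "load_gene_trait_evidence",
    "filter_gene_trait_evidence",
    "load_organ_annotations",
    "attach_organ_annotations",
    "read_gene_sets",
    "write_gene_sets",
]


@dataclass(frozen=True)
class GeneTraitEvidence:
    """One gene–trait association with its evidence source and score."""

    gene: str
    trait_id: str
    trait_class: str  # "human" | "mouse"
    source: str
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise InputError(f"evidence score {self.score} outside [0, 1]")
        if not self.source:
            raise InputError("evidence source must be nonempty")


@dataclass(frozen=True)
class TraitSeedSet:
    """A trait (human disease or mouse phenotype) with its seed genes.

    Human traits may carry organ-phenotype annotations; mouse traits carry
    none. Seed sets are immutable frozensets.
    """

    trait_id: str
    trait_class: str
    seed_genes: frozenset[str]
    organ_phenotypes: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.seed_genes:
            raise InputError(f"trait {self.trait_id!r} has an empty seed set")
        unknown = self.organ_phenotypes - set(ORGAN_PHENOTYPES)
        if unknown:
            raise InputError(f"unknown organ phenotype(s) {sorted(unknown)}")

    def with_organs(self, organs: Iterable[str]) -> "TraitSeedSet":
        return TraitSeedSet(self.trait_id, self.trait_class,
                            self.seed_genes, frozenset(organs))


# ---------------------------------------------------------------------------
# network edge lists


def load_network(edge_list_path: str | Path, min_weight: float = 0.0) -> InteractionNetwork:
    """Load a TSV edge list, dropping edges below ``min_weight`` (inclusive keep).

    Self-loops are removed and duplicate unordered pairs collapsed to the
    maximum weight. Raises InputError on empty input or when no edges
    survive, ParseError (with line number) on malformed rows.
    """
    path = Path(edge_list_path)
    edges: list[tuple[str, str, float]] = []
    with path.open(encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise InputError(f"{path}: empty edge list")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ParseError(f"{path}: expected >= 3 columns, got {len(row)}", lineno)
            a, b = row[0].strip(), row[1].strip()
            try:
                w = float(row[2])
            except ValueError:
                raise ParseError(f"{path}: non-numeric weight {row[2]!r}", lineno) from None
            if not a or not b:
                raise ParseError(f"{path}: empty gene identifier", lineno)
            if w >= min_weight and a != b:
                edges.append((a, b, w))
    if not edges:
        raise InputError(f"{path}: no edges survive min_weight={min_weight}")
    return InteractionNetwork.from_edges(edges)


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in network.iter_edges():
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


# ---------------------------------------------------------------------------
# gene–trait evidence


def load_gene_trait_evidence(path: str | Path) -> list[GeneTraitEvidence]:
    path = Path(path)
    records: list[GeneTraitEvidence] = []
    with path.open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "trait_id", "trait_class", "source", "score"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(GeneTraitEvidence(
                    gene=row["gene"].strip(),
                    trait_id=row["trait_id"].strip(),
                    trait_class=row["trait_class"].strip(),
                    source=row["source"].strip(),
                    score=float(row["score"])))
            except (ValueError, InputError) as exc:
                raise ParseError(f"{path}: {exc}", lineno) from None
    return records


DEFAULT_MIN_SEEDS = {"human": 2, "mouse": 10}


def filter_gene_trait_evidence(
    records: Sequence[GeneTraitEvidence],
    default_threshold: float = 0.5,
    per_source_thresholds: Mapping[str, float] | None = None,
    min_seeds: int | Mapping[str, int] | None = None,
    network: InteractionNetwork | None = None,
) -> list[TraitSeedSet]:
    """Apply the evidence-score and minimum-seed filters.

    A record survives iff its score *strictly* exceeds its source's
    threshold (per-source override, else ``default_threshold``); traits with
    fewer surviving genes than the class minimum (human 2, mouse 10 by
    default) are dropped. If a ``network`` is supplied, genes absent from it
    are flagged with a warning but retained (they are removed at propagation
    time).
    """
    per_source = dict(per_source_thresholds or {"ClinVar": 0.8})
    for thr in [default_threshold, *per_source.values()]:
        if not (0.0 <= thr <= 1.0):
            raise InputError(f"threshold {thr} outside [0, 1]")
    if min_seeds is None:
        minima = dict(DEFAULT_MIN_SEEDS)
    elif isinstance(min_seeds, Mapping):
        minima = {**DEFAULT_MIN_SEEDS, **min_seeds}
    else:
        minima = {"human": int(min_seeds), "mouse": int(min_seeds)}

    by_trait: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        thr = per_source.get(rec.source, default_threshold)
        if rec.score > thr:
            by_trait.setdefault((rec.trait_id, rec.trait_class), set()).add(rec.gene)

    traits: list[TraitSeedSet] = []
    for (trait_id, trait_class) in sorted(by_trait):
        genes = by_trait[(trait_id, trait_class)]
        need = minima.get(trait_class, 1)
        if len(genes) < need:
            logger.info("dropping trait %s (%d < %d seeds)", trait_id, len(genes), need)
            continue
        if network is not None:
            missing = {g for g in genes if g not in network}
            if missing:
                logger.warning("trait %s: %d seed(s) absent from network",
                               trait_id, len(missing))
        traits.append(TraitSeedSet(trait_id, trait_class, frozenset(genes)))
    if not traits:
        logger.warning("no traits survive evidence filtering")
    return traits


def load_organ_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a (trait_id, organ) TSV into trait → organ-label set."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"trait_id", "organ"} <= set(reader.fieldnames):
            raise InputError(f"{path}: header must contain trait_id, organ")
        for row in reader:
            out.setdefault(row["trait_id"].strip(), set()).add(row["organ"].strip())
    return {k: frozenset(v) for k, v in out.items()}


def attach_organ_annotations(traits: Sequence[TraitSeedSet],
                             annotations: Mapping[str, Iterable[str]]) -> list[TraitSeedSet]:
    return [t.with_organs(annotations.get(t.trait_id, ())) if t.trait_class == "human" else t
            for t in traits]


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(gmt_path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file (name, description, genes…) into name → gene set."""
    path = Path(gmt_path)
    sets: dict[str, frozenset[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: GMT line needs name, description, >=1 gene", lineno)
            name = parts[0]
            if name in sets:
                raise InputError(f"{path}: duplicate gene-set name {name!r}")
            genes = frozenset(g for g in parts[2:] if g)
            sets[name] = genes
    return sets


def write_gene_sets(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        for name in gene_sets:
            genes = "\t".join(sorted(set(gene_sets[name])))
            fh.write(f"{name}\tna\t{genes}\n")
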