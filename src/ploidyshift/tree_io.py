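"""Tree and trait-table input/output, joint validation, and tip matching.

The matching step mirrors how comparative datasets are usually assembled:
tree tips are species names, the trait database has records at species,
genus or family resolution, and overlap is maximised by an iterative match —
exact species matches first, then genera with no species-level match are
collapsed to a single tip and matched against genus-level information, then
the same at family level.  Multiple matching records contribute the mean
diploid chromosome count; discrete traits (reproductive system) must agree
across the records behind one tip, anything else is treated as a data error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .tree import MissingBranchLengthError, TimeTree

__all__ = [
    "DIPLOID",
    "HAPLODIPLOID",
    "SYSTEM_STATES",
    "TraitRecord",
    "MatchedDataset",
    "TreeFormatError",
    "TraitTableError",
    "MatchConflictError",
    "read_tree_set",
    "write_tree_set",
    "read_trait_table",
    "write_trait_table",
    "normalize_label",
    "match_tips",
    "prune_to",
]

DIPLOID = 0
HAPLODIPLOID = 1
SYSTEM_STATES = ("diplodiploid", "haplodiploid")

TRAIT_COLUMNS = [
    "taxon",
    "infraorder",
    "family",
    "genus",
    "species",
    "system",
    "count_2n",
    "sex_determination",
]


class TreeFormatError(ValueError):
    """Input tree file could not be parsed."""


class TraitTableError(ValueError):
    """Trait table fails validation."""


class MatchConflictError(ValueError):
    """Records matched to one tip disagree on a discrete trait."""


@dataclass
class TraitRecord:
    """One row of the trait database.

    ``system`` is the binary reproductive system ("haplodiploid" covers both
    arrhenotoky and paternal genome elimination); ``count_2n`` is the diploid
    chromosome count in females.
    """

    taxon: str
    system: str
    count_2n: float | None = None
    infraorder: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None
    sex_determination: str | None = None

    def __post_init__(self) -> None:
        if self.system not in SYSTEM_STATES:
            raise TraitTableError(
                f"record {self.taxon!r}: system must be one of {SYSTEM_STATES}, got {self.system!r}"
            )
        if self.count_2n is not None and not (
            float(self.count_2n).is_integer() and 2 <= self.count_2n <= 200
        ):
            raise TraitTableError(
                f"record {self.taxon!r}: count_2n must be an integer in [2, 200], got {self.count_2n}"
            )
        if self.sex_determination not in (None, "XY", "XO"):
            raise TraitTableError(
                f"record {self.taxon!r}: sex_determination must be XY or XO, got "
                f"{self.sex_determination!r}"
            )


@dataclass
class MatchedDataset:
    """A tree pruned to matched tips plus one trait row per tip.

    ``traits`` is indexed 0..n_tips-1 in tip order with columns ``taxon``
    (equal to the tip label), ``system``, ``count_2n``, ``match_level``,
    taxonomy columns and ``n_records``.  ``metadata`` records conventions
    that are a choice rather than a fact of the input, e.g. that collapsed
    genus/family tips end at the collapsed clade's crown depth.
    """

    tree: TimeTree
    traits: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def systems(self) -> np.ndarray:
        """Tip systems encoded diplodiploid=0, haplodiploid=1, in tip order."""
        return np.asarray(
            [SYSTEM_STATES.index(s) for s in self.traits["system"]], dtype=np.int64
        )

    @property
    def count_2n(self) -> np.ndarray:
        return self.traits["count_2n"].to_numpy(dtype=float)


# ---------------------------------------------------------------------- #
# trees
# ---------------------------------------------------------------------- #
def _detect_schema(path: str | Path) -> str:
    with open(path) as fh:
        head = fh.read(512).lstrip()
    return "nexus" if head.lower().startswith("#nexus") else "newick"


def read_tree_set(path: str | Path, format: str | None = None) -> list[TimeTree]:
    """Read one or more trees from a Newick or Nexus file.

    ``format`` is auto-detected from the file head when not given.  Trees
    without branch lengths are rejected: every downstream method is
    time-calibrated.
    """
    schema = format or _detect_schema(path)
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {schema!r}")
    try:
        tl = dendropy.TreeList.get(
            path=str(path),
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except MissingBranchLengthError:
        raise
    except Exception as exc:  # dendropy raises schema-specific DataErrors
        raise TreeFormatError(f"could not parse {path} as {schema}: {exc}") from exc
    if len(tl) == 0:
        raise TreeFormatError(f"no trees found in {path}")
    return [TimeTree.from_dendropy(t) for t in tl]


def write_tree_set(trees: Sequence[TimeTree], path: str | Path, format: str = "newick") -> None:
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(t.to_dendropy(taxon_namespace=tns))
    kwargs = {"unquoted_underscores": True}
    if format == "newick":
        kwargs["suppress_rooting"] = True
    tl.write(path=str(path), schema=format, **kwargs)


# ---------------------------------------------------------------------- #
# trait tables
# ---------------------------------------------------------------------- #
def _frame_to_records(df: pd.DataFrame) -> list[TraitRecord]:
    recs = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in TRAIT_COLUMNS:
            val = row.get(col)
            if isinstance(val, float) and np.isnan(val):
                val = None
            if val == "":
                val = None
            kwargs[col] = val
        if kwargs["count_2n"] is not None:
            kwargs["count_2n"] = float(kwargs["count_2n"])
        recs.append(TraitRecord(**kwargs))
    return recs


def read_trait_table(path: str | Path) -> list[TraitRecord]:
    """Read a CSV/TSV trait table (columns: taxon, infraorder, family, genus,
    species, system, count_2n, sex_determination) into records, validating
    each row."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"taxon", "system"} - set(df.columns)
    if missing:
        raise TraitTableError(f"trait table missing required columns: {sorted(missing)}")
    for col in TRAIT_COLUMNS:
        if col not in df.columns:
            df[col] = None
    return _frame_to_records(df[TRAIT_COLUMNS])


def write_trait_table(records: Iterable[TraitRecord] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([vars(r) for r in records])
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------- #
# matching
# ---------------------------------------------------------------------- #
_WS = re.compile(r"[\s_]+")


def normalize_label(label: str) -> str:
    """Case-insensitive comparison form: underscores as spaces, collapsed."""
    return _WS.sub(" ", str(label)).strip().lower()


def _genus_of(norm_label: str) -> str:
    return norm_label.split(" ")[0] if norm_label else ""


def _aggregate(tip_label: str, recs: list[TraitRecord], level: str) -> dict:
    systems = {r.system for r in recs}
    if len(systems) != 1:
        detail = ", ".join(f"{r.taxon}={r.system}" for r in recs)
        raise MatchConflictError(
            f"records matched to tip {tip_label!r} disagree on reproductive system: {detail}"
        )
    sexdet = {r.sex_determination for r in recs if r.sex_determination is not None}
    counts = [r.count_2n for r in recs if r.count_2n is not None]

    def _uniq(vals: set) -> str | None:
        return vals.pop() if len(vals) == 1 else None

    return {
        "taxon": tip_label,
        "system": systems.pop(),
        "count_2n": float(np.mean(counts)) if counts else np.nan,
        "match_level": level,
        "infraorder": _uniq({r.infraorder for r in recs if r.infraorder}),
        "family": _uniq({r.family for r in recs if r.family}),
        "genus": _uniq({r.genus for r in recs if r.genus}),
        "species": _uniq({r.species for r in recs if r.species}),
        "sex_determination": _uniq(sexdet) if sexdet else None,
        "n_records": len(recs),
    }


def _collapse_group(tree: TimeTree, tips: list[str], new_label: str) -> TimeTree:
    """Collapse a set of tips to one tip named ``new_label``.

    If the tips are monophyletic the whole clade is replaced by a tip ending
    at the clade's crown depth (its stem is retained).  A non-monophyletic
    group — rare, but possible on any single tree — degrades gracefully: the
    first tip is renamed and the rest are dropped later by pruning.
    """
    idx = [tree.tip_index(t) for t in tips]
    if len(idx) == 1:
        tree = tree.copy()
        tree.tip_labels[idx[0]] = new_label
        return tree
    m = tree.mrca(idx)
    if sorted(tree.tips_below(m)) == sorted(idx):
        new_tree, _ = tree.collapse_clade(m, new_label)
        return new_tree
    tree = tree.copy()
    tree.tip_labels[idx[0]] = new_label
    return tree


def match_tips(tree: TimeTree, table: Sequence[TraitRecord]) -> MatchedDataset:
    """Iteratively match tree tips against a trait database.

    1. Exact species matches (labels compared case-insensitively with
       underscores treated as spaces).
    2. Each genus on the tree with zero species-level matches is collapsed
       to a single tip and matched against all records of that genus.
    3. Likewise at family level: tips identified only to family resolution
       (their first name token is a family in the table) are collapsed and
       matched against all records of that family.

    Multiple matching records contribute their mean chromosome count; they
    must agree on the reproductive system.  Unmatched tips are pruned.
    """
    if not table:
        raise ValueError("empty trait table")
    recs = list(table)
    by_taxon: dict[str, list[TraitRecord]] = {}
    by_genus: dict[str, list[TraitRecord]] = {}
    by_family: dict[str, list[TraitRecord]] = {}
    for r in recs:
        by_taxon.setdefault(normalize_label(r.taxon), []).append(r)
        g = normalize_label(r.genus) if r.genus else _genus_of(normalize_label(r.taxon))
        if g:
            by_genus.setdefault(g, []).append(r)
        if r.family:
            by_family.setdefault(normalize_label(r.family), []).append(r)

    rows: list[dict] = []
    # pass 1: exact species matches
    species_matched: set[str] = set()
    genus_has_species_match: set[str] = set()
    for lab in tree.tip_labels:
        nl = normalize_label(lab)
        if nl in by_taxon:
            rows.append(_aggregate(lab, by_taxon[nl], "species"))
            species_matched.add(lab)
            genus_has_species_match.add(_genus_of(nl))

    # pass 2: genus collapsing
    work = tree
    matched_labels = set(species_matched)
    unmatched = [lab for lab in tree.tip_labels if lab not in species_matched]
    genus_groups: dict[str, list[str]] = {}
    for lab in unmatched:
        g = _genus_of(normalize_label(lab))
        if g and g not in genus_has_species_match:
            genus_groups.setdefault(g, []).append(lab)
    family_groups: dict[str, list[str]] = {}
    for g, tips in sorted(genus_groups.items()):
        if g in by_genus:
            new_label = g.capitalize()
            work = _collapse_group(work, tips, new_label)
            rows.append(_aggregate(new_label, by_genus[g], "genus"))
            matched_labels.add(new_label)
        elif g in by_family:
            # tip identified only to family level (e.g. "Parasitidae sp.")
            family_groups.setdefault(g, []).extend(tips)

    # pass 3: family collapsing
    for fam, tips in sorted(family_groups.items()):
        tips = [t for t in tips if t in work.tip_labels]
        if not tips:
            continue
        new_label = fam.capitalize()
        work = _collapse_group(work, tips, new_label)
        rows.append(_aggregate(new_label, by_family[fam], "family"))
        matched_labels.add(new_label)

    keep = [lab for lab in work.tip_labels if lab in matched_labels]
    if not keep:
        raise ValueError("no overlap between tree tips and trait table")
    if len(keep) >= 2 and len(keep) < work.n_tips:
        work, _ = work.prune_to_tips(keep)
    traits = pd.DataFrame(rows)
    order = {lab: i for i, lab in enumerate(work.tip_labels)}
    traits = traits[traits["taxon"].isin(order)]
    traits = traits.sort_values("taxon", key=lambda s: s.map(order)).reset_index(drop=True)
    meta = {
        "n_species_matches": int((traits["match_level"] == "species").sum()),
        "n_genus_matches": int((traits["match_level"] == "genus").sum()),
        "n_family_matches": int((traits["match_level"] == "family").sum()),
        "collapsed_tip_convention": (
            "collapsed genus/family tips end at the collapsed clade's crown depth "
            "(stem branch retained); this is a package convention, not a property "
            "of the input data"
        ),
    }
    return MatchedDataset(tree=work, traits=traits, metadata=meta)


def prune_to(tree: TimeTree, keep_labels: Iterable[str]) -> TimeTree:
    """Induced subtree on ``keep_labels``; patristic distances among kept
    tips are preserved (suppressed branches are summed)."""
    labels = list(keep_labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels to keep")
    if set(labels) == set(tree.tip_labels):
        return tree.copy()
    pruned, _ = tree.prune_to_tips(labels)
    return pruned
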