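"""Genealogical Concordance Phylogenetic Species Recognition (GCPSR).

Species are delimited as clades that are well supported (BS >= 70 and
PP >= 0.95) in at least one single-locus genealogy and contradicted by
none; lineages whose support comes from a single independent linkage
group (ITS and LSU are inherited together and count once) are demoted to
*putative* phylogenetic species.  Support classes follow the usual
three-band convention:

===========  ==========  ============
class        bootstrap   posterior
===========  ==========  ============
strong       >= 90       >= 0.99
medium       70–89       0.95–0.98
weak         50–69       0.80–0.94
unsupported  below       below
===========  ==========  ============

When both metrics are present the weaker band is binding (the bands are
conjunctions); when one is absent the class is taken from the available
metric alone and flagged as single-metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "Genealogy",
    "SupportClass",
    "Lineage",
    "DelimitationResult",
    "parse_annotated_tree",
    "classify_support",
    "assess_clade_against_genealogy",
    "delimit_species",
    "count_parsimony_informative",
]

_CATEGORIES = ("unsupported", "weak", "medium", "strong")


@dataclass(frozen=True)
class SupportClass:
    category: str
    well_supported: bool
    single_metric: bool = False


@dataclass
class Genealogy:
    """One locus's rooted, outgroup-rooted genealogy with clade supports.

    ``clades`` maps each internal clade (frozenset of ingroup taxa) to its
    (BS, PP) pair; either value may be ``None`` (supports below the usual
    reporting floor are simply absent from published trees).
    """

    locus: str
    linkage_group: str
    taxa: frozenset[str]
    outgroup: str
    clades: dict[frozenset[str], tuple[float | None, float | None]]
    newick: str | None = None

    @property
    def ingroup(self) -> frozenset[str]:
        return self.taxa - {self.outgroup}

    def well_supported_clades(self) -> dict[frozenset[str], tuple]:
        out = {}
        for clade, (bs, pp) in self.clades.items():
            if bs is None and pp is None:
                continue
            if classify_support(bs, pp).well_supported:
                out[clade] = (bs, pp)
        return out


def classify_support(
    bs: float | None, pp: float | None
) -> SupportClass:
    """Class of a clade given bootstrap (0-100) and posterior (0-1)."""
    if bs is None and pp is None:
        return SupportClass("unsupported", False, single_metric=True)
    if bs is not None and not 0 <= bs <= 100:
        raise ValueError(f"bootstrap {bs} outside [0, 100]")
    if pp is not None and not 0 <= pp <= 1:
        raise ValueError(f"posterior {pp} outside [0, 1]")

    def bs_band(v):
        return "strong" if v >= 90 else "medium" if v >= 70 else "weak" if v >= 50 else "unsupported"

    def pp_band(v):
        return "strong" if v >= 0.99 else "medium" if v >= 0.95 else "weak" if v >= 0.80 else "unsupported"

    if bs is None or pp is None:
        cat = bs_band(bs) if bs is not None else pp_band(pp)
        return SupportClass(cat, cat in ("strong", "medium"), single_metric=True)
    cat = min(bs_band(bs), pp_band(pp), key=_CATEGORIES.index)
    return SupportClass(cat, cat in ("strong", "medium"))


def _parse_label(label: str | None, convention: str):
    if label is None or label == "":
        return None, None
    try:
        if convention == "bs/pp":
            if "/" not in label:
                raise ValueError("expected BS/PP label")
            bs_s, pp_s = label.split("/", 1)
            bs = float(bs_s) if bs_s not in ("", "-") else None
            pp = float(pp_s) if pp_s not in ("", "-") else None
        elif convention == "bs":
            bs, pp = float(label), None
        elif convention == "pp":
            bs, pp = None, float(label)
        else:
            raise ValueError(f"unknown support convention {convention!r}")
    except ValueError as exc:
        raise ValueError(f"unparseable support label {label!r}: {exc}") from exc
    if bs is not None and not 0 <= bs <= 100:
        raise ValueError(f"bootstrap {bs} outside [0, 100] in label {label!r}")
    if pp is not None and not 0 <= pp <= 1:
        raise ValueError(f"posterior {pp} outside [0, 1] in label {label!r}")
    return bs, pp


def parse_annotated_tree(
    newick_text: str,
    locus: str = "locus",
    linkage_group: str | None = None,
    support_convention: str = "bs/pp",
    outgroup: str = "OUT",
) -> Genealogy:
    """Parse a Newick genealogy whose internal node labels carry support.

    Labels are either ``BS/PP`` (e.g. ``95/0.99``), bare BS, or bare PP,
    per ``support_convention``; missing labels leave both supports absent.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate taxa in tree: {exc}") from exc
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {t for t in taxa if taxa.count(t) > 1}
    if dupes:
        raise ValueError(f"duplicate taxa in tree: {sorted(dupes)}")
    taxon_set = frozenset(taxa)
    if outgroup not in taxon_set:
        raise ValueError(f"outgroup {outgroup!r} absent from tree taxa")
    clades: dict[frozenset[str], tuple] = {}
    for node in tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if leaves == taxon_set:  # root
            continue
        bs, pp = _parse_label(node.label, support_convention)
        if leaves in clades:
            old = clades[leaves]
            bs = bs if bs is not None else old[0]
            pp = pp if pp is not None else old[1]
        clades[leaves] = (bs, pp)
    return Genealogy(
        locus=locus,
        linkage_group=linkage_group or locus,
        taxa=taxon_set,
        outgroup=outgroup,
        clades=clades,
    )


def assess_clade_against_genealogy(
    clade_taxa: Iterable[str], genealogy: Genealogy
) -> str:
    """Verdict of one genealogy on a candidate lineage.

    Returns ``supported`` / ``compatible`` / ``contradicted`` /
    ``uninformative``.  Contradiction requires the conflicting clade of
    the genealogy to itself be well supported: an unsupported conflicting
    topology is merely ``compatible``.
    """
    restriction = frozenset(clade_taxa) & genealogy.ingroup
    if len(restriction) < 2:
        return "uninformative"
    if restriction == genealogy.ingroup:
        return "uninformative"
    present = {c - {genealogy.outgroup} for c in genealogy.clades}
    if restriction in present:
        return "supported"
    for clade in genealogy.well_supported_clades():
        w = clade - {genealogy.outgroup}
        inter = w & restriction
        if inter and not w <= restriction and not restriction <= w:
            return "contradicted"
    return "compatible"


@dataclass
class Lineage:
    taxa: frozenset[str]
    status: str  # "phylogenetic_species" | "putative_species"
    supporting_loci: list[str]
    linkage_groups: list[str]
    contradicting_loci: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    substructure: list[frozenset[str]] = field(default_factory=list)


@dataclass
class DelimitationResult:
    lineages: list[Lineage]
    unassigned: list[str]

    @property
    def phylogenetic_species(self) -> list[Lineage]:
        return [l for l in self.lineages if l.status == "phylogenetic_species"]

    @property
    def putative_species(self) -> list[Lineage]:
        return [l for l in self.lineages if l.status == "putative_species"]

    def partition(self) -> set[frozenset[str]]:
        return {l.taxa for l in self.lineages}


def _support_strength(bs, pp) -> float:
    vals = []
    if bs is not None:
        vals.append(bs / 100.0)
    if pp is not None:
        vals.append(pp)
    return min(vals) if vals else 0.0


def delimit_species(
    genealogies: Sequence[Genealogy],
    multilocus_tree: Genealogy | None = None,
) -> DelimitationResult:
    """Delimit independent evolutionary lineages across genealogies.

    Candidate clades are the well-supported clades of every single-locus
    genealogy (outgroup excluded); a candidate is accepted unless some
    genealogy contradicts it.  Identical taxon sets are merged across
    loci, mutually incompatible accepted clades are resolved
    deterministically (more independent supporting linkage groups, then
    higher minimum support, then smaller clade, then lexicographic), and
    lineages are reported at the maximal accepted clades, with nested
    accepted clades retained as substructure.  A lineage whose support
    all comes from one linkage group is a putative species.  A supplied
    multilocus genealogy only flags (never removes) lineages it
    contradicts.
    """
    if not genealogies:
        raise ValueError("need at least one genealogy")
    if len(genealogies) > 1:
        # concordance needs a connected taxon-overlap graph (union-find)
        n = len(genealogies)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in itertools.combinations(range(n), 2):
            if genealogies[i].ingroup & genealogies[j].ingroup:
                parent[find(i)] = find(j)
        if len({find(i) for i in range(n)}) > 1:
            raise ValueError(
                "no basis for concordance: genealogies share no taxa"
            )

    # gather candidates, merging identical taxon sets across loci
    cands: dict[frozenset[str], dict] = {}
    for g in genealogies:
        for clade, (bs, pp) in g.well_supported_clades().items():
            taxa = clade - {g.outgroup}
            if len(taxa) < 2 or taxa == g.ingroup:
                continue
            entry = cands.setdefault(
                taxa, {"loci": [], "groups": set(), "strength": 1.0, "flags": set()}
            )
            entry["loci"].append(g.locus)
            entry["groups"].add(g.linkage_group)
            entry["strength"] = min(entry["strength"], _support_strength(bs, pp))
            if bs is None or pp is None:
                entry["flags"].add("single_metric_support")

    accepted = {}
    for taxa, entry in cands.items():
        verdicts = {
            g.locus: assess_clade_against_genealogy(taxa, g)
            for g in genealogies
        }
        if any(v == "contradicted" for v in verdicts.values()):
            continue
        accepted[taxa] = entry

    # resolve mutual incompatibilities deterministically
    def priority(item):
        taxa, entry = item
        return (
            -len(entry["groups"]),
            -entry["strength"],
            len(taxa),
            tuple(sorted(taxa)),
        )

    kept: list[tuple[frozenset[str], dict]] = []
    for taxa, entry in sorted(accepted.items(), key=priority):
        if all(
            not (taxa & other) or taxa <= other or other <= taxa
            for other, _e in kept
        ):
            kept.append((taxa, entry))

    # maximal kept clades are the lineages; nested ones are substructure
    lineages = []
    for taxa, entry in kept:
        if any(taxa < other for other, _e in kept):
            continue
        nested = [t for t, _e in kept if t < taxa]
        status = (
            "putative_species"
            if len(entry["groups"]) == 1
            else "phylogenetic_species"
        )
        flags = sorted(entry["flags"])
        if multilocus_tree is not None:
            verdict = assess_clade_against_genealogy(taxa, multilocus_tree)
            if verdict == "contradicted":
                flags.append("contradicted_by_multilocus_tree")
        lineages.append(
            Lineage(
                taxa=taxa,
                status=status,
                supporting_loci=sorted(entry["loci"]),
                linkage_groups=sorted(entry["groups"]),
                flags=flags,
                substructure=sorted(nested, key=lambda t: tuple(sorted(t))),
            )
        )
    lineages.sort(key=lambda l: tuple(sorted(l.taxa)))
    all_ingroup = set().union(*(g.ingroup for g in genealogies))
    assigned = set().union(*(l.taxa for l in lineages)) if lineages else set()
    return DelimitationResult(
        lineages=lineages, unassigned=sorted(all_ingroup - assigned)
    )


_UNAMBIGUOUS = frozenset("ACGT")


def count_parsimony_informative(
    alignment: Sequence[str],
) -> tuple[int, float]:
    """Count parsimony-informative columns of a DNA alignment.

    A column is informative iff at least two distinct unambiguous states
    (A/C/G/T) each occur in at least two sequences; gaps and ambiguity
    codes are treated as missing.  Returns (count, fraction of columns).
    """
    rows = [r.upper() for r in alignment]
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    count = 0
    for j in range(ncol):
        tally: dict[str, int] = {}
        for r in rows:
            c = r[j]
            if c in _UNAMBIGUOUS:
                tally[c] = tally.get(c, 0) + 1
        if sum(1 for v in tally.values() if v >= 2) >= 2:
            count += 1
    return count, (count / ncol if ncol else 0.0)
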