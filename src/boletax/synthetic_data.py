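"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, all deterministic under a fixed seed:

* multi-locus genealogy sets with a known species partition, tunable
  inter-locus concordance and support ranges, and per-locus taxon
  masking — emulating a three-linkage-group study design (ITS-LSU
  inherited together, tef1-α, rpb2);
* ITS marker sequences with a planted AC microsatellite in ITS1 and a
  planted minisatellite array (given consensus, fractional copy number,
  mutation rates) in ITS2, plus exact truth records;
* bivariate-Gaussian (length, width) spore measurements grouped
  collection → basidiome.

No molecular evolution is simulated along the trees: topologies are
random join (coalescent-style) and serve purely as delimitation inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gcpsr import Genealogy, parse_annotated_tree
from .morphometrics import MeasurementSet
from .tandem_repeats import MarkerRecord

__all__ = [
    "GenealogySimParams",
    "InsertionSimParams",
    "SporeSimParams",
    "simulate_genealogy_set",
    "simulate_marker_sequences",
    "simulate_spore_measurements",
    "LEFT_FLANK",
    "RIGHT_FLANK",
    "DEFAULT_MINISAT_CONSENSUS",
]

#: fixed synthetic 100-bp flanks, verified repeat-free under both the
#: 2-7-7 and 2-3-5 weight settings and unable to extend an AC-phase run
#: across the junction; used when embedding repeat constructs
LEFT_FLANK = (
    "GATCATGGTCTCGGAAAGGTGATTGGAACCATCGACAGTAGACAGCCCCC"
    "GTCAAAAAAGTTGGCTGGGTGTGGCTGCCCGCGGTCGTCCCCGCTCAAAG"
)
RIGHT_FLANK = (
    "GGAGGCGGTAGGCAGTAGATGCTGTAGCCACGGACCACCAATGACAGCCA"
    "GGGGTTCTACGTGCCTCAGTTGCCACCCTATGTCCTAATCCGGGCGACCG"
)

#: 80-bp minisatellite core motif of the kind carried by bolete ITS2
#: insertions; the default unit planted in ITS2
DEFAULT_MINISAT_CONSENSUS = (
    "GGGACTCGAGCGAAGGGTCGGCTTAGCTATTAGTTGGTCG"
    "TGAGGCCAGCGAACGCGGTCGGGCTGGGTCTCGAGCTTCA"
)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# genealogy sets


@dataclass
class GenealogySimParams:
    """Study design for a multi-locus genealogy simulation.

    ``loci`` is a list of (locus name, linkage group) pairs; ITS and LSU
    sharing a linkage group is declared here.  ``concordance_prob`` is
    the probability, independent per species per locus, that the locus
    renders a true species monophyletic.  ``support_model`` gives the
    (BS range, PP range) drawn for true-species clades and for all other
    clades.
    """

    true_partition: Mapping[str, str]
    loci: Sequence[tuple[str, str]] = (
        ("ITS", "ITS-LSU"),
        ("LSU", "ITS-LSU"),
        ("tef1", "tef1"),
        ("rpb2", "rpb2"),
    )
    concordance_prob: float = 1.0
    support_model: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: {
            "true": ((95.0, 100.0), (0.99, 1.0)),
            "other": ((5.0, 69.0), (0.50, 0.94)),
        }
    )
    masking: Mapping[str, frozenset[str]] = field(default_factory=dict)
    outgroup: str = "OUT"
    seed: int = 0

    def __post_init__(self):
        if not self.true_partition:
            raise ValueError("true_partition must not be empty")
        if not 0.0 <= self.concordance_prob <= 1.0:
            raise ValueError("concordance_prob must be in [0, 1]")
        for key in ("true", "other"):
            (b0, b1), (p0, p1) = self.support_model[key]
            if not (0 <= b0 <= b1 <= 100):
                raise ValueError(f"BS range for {key!r} outside [0, 100]")
            if not (0 <= p0 <= p1 <= 1):
                raise ValueError(f"PP range for {key!r} outside [0, 1]")
        if self.outgroup in self.true_partition:
            raise ValueError("outgroup id collides with a specimen id")


class _Node:
    __slots__ = ("children", "name", "species_root")

    def __init__(self, name=None, children=None, species_root=False):
        self.name = name
        self.children = children or []
        self.species_root = species_root

    @property
    def is_leaf(self):
        return not self.children


def _random_join(nodes: list[_Node], rng) -> _Node:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(_Node(children=[a, b]))
    return nodes[0]


def _serialize(node: _Node, labels: dict) -> str:
    if node.is_leaf:
        return node.name
    inner = ",".join(_serialize(c, labels) for c in node.children)
    return f"({inner}){labels.get(id(node), '')}"


def simulate_genealogy_set(
    params: GenealogySimParams,
) -> tuple[list[Genealogy], dict[str, str]]:
    """Simulate one rooted genealogy per locus.

    Each true species is rendered monophyletic with probability
    ``concordance_prob`` (independent per species per locus); when
    monophyletic its clade draws BS/PP from the "true" support range,
    every other internal clade from the "other" range.  Masked specimens
    are absent from the locus's tree; the outgroup is appended to every
    tree.  Output is byte-identical under a fixed seed.
    """
    partition = dict(params.true_partition)
    species_members: dict[str, list[str]] = {}
    for spec, sp in sorted(partition.items()):
        species_members.setdefault(sp, []).append(spec)
    if len(species_members) < 2 or len(partition) < 3:
        raise ValueError("need >= 2 species and >= 3 specimens")
    for sp, members in species_members.items():
        if all(
            set(members) <= set(params.masking.get(locus, frozenset()))
            for locus, _lg in params.loci
        ):
            raise ValueError(
                f"species {sp!r} is masked from every locus: nothing to infer"
            )
    rng = np.random.default_rng(params.seed)
    genealogies = []
    for locus, linkage_group in params.loci:
        masked = set(params.masking.get(locus, frozenset()))
        units: list[_Node] = []
        species_roots: list[_Node] = []
        for sp in sorted(species_members):
            present = [m for m in species_members[sp] if m not in masked]
            if not present:
                continue
            if len(present) == 1:
                units.append(_Node(name=present[0]))
                continue
            concordant = rng.random() < params.concordance_prob
            leaves = [_Node(name=m) for m in present]
            if concordant:
                sub = _random_join(leaves, rng)
                sub.species_root = True
                species_roots.append(sub)
                units.append(sub)
            else:
                units.extend(leaves)
        if not units:
            continue
        ingroup = _random_join(units, rng) if len(units) > 1 else units[0]
        root = _Node(children=[ingroup, _Node(name=params.outgroup)])
        labels: dict[int, str] = {}
        stack = [root]
        internal = []
        while stack:  # preorder, deterministic
            n = stack.pop()
            if not n.is_leaf:
                if n is not root:
                    internal.append(n)
                stack.extend(reversed(n.children))
        for n in internal:
            kind = "true" if n.species_root else "other"
            (b0, b1), (p0, p1) = params.support_model[kind]
            bs = int(round(rng.uniform(b0, b1)))
            pp = math.floor(rng.uniform(p0, p1) * 100) / 100
            labels[id(n)] = f"{bs}/{pp:.2f}"
        newick = _serialize(root, labels) + ";"
        g = parse_annotated_tree(
            newick,
            locus=locus,
            linkage_group=linkage_group,
            support_convention="bs/pp",
            outgroup=params.outgroup,
        )
        g.newick = newick
        genealogies.append(g)
    return genealogies, partition


# ---------------------------------------------------------------------------
# marker sequences with planted insertions


@dataclass
class InsertionSimParams:
    """Planted-insertion design for synthetic ITS sequences."""

    backbone_length: int = 900
    its_annotation: Mapping[str, tuple[int, int]] | None = None
    minis_consensus: str = DEFAULT_MINISAT_CONSENSUS
    minis_copies: float = 2.8
    minis_sub_rate: float = 0.05
    minis_indel_rate: float = 0.0
    micro_unit: str = "AC"
    micro_length: int = 26
    n_sequences: int = 5
    seed: int = 0

    def __post_init__(self):
        if set(self.minis_consensus) - set(_BASES) or not self.minis_consensus:
            raise ValueError("minisatellite consensus must be non-empty ACGT")
        if set(self.micro_unit) - set(_BASES) or not self.micro_unit:
            raise ValueError("microsatellite unit must be non-empty ACGT")
        if self.micro_length < 0 or self.micro_length % 2:
            raise ValueError("micro_length must be even and >= 0")
        for r in (self.minis_sub_rate, self.minis_indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("mutation rates must be in [0, 1]")
        if self.minis_copies < 1.0:
            raise ValueError("minis_copies must be >= 1")
        if self.its_annotation is None:
            L = self.backbone_length
            self.its_annotation = {
                "ITS1": (50, max(60, L // 3)),
                "5.8S": (max(60, L // 3), max(70, L // 2)),
                "ITS2": (max(70, L // 2), L - 40),
            }
        prev_end = 0
        for region in ("ITS1", "5.8S", "ITS2"):
            s, e = self.its_annotation[region]
            if not (prev_end <= s < e <= self.backbone_length):
                raise ValueError(
                    "annotation intervals must be ordered, non-overlapping "
                    "and within the backbone"
                )
            prev_end = e


def _guard_base(avoid: str) -> str:
    for b in "GTAC":
        if b != avoid:
            return b
    return "G"


def _mutate(planted: str, sub_rate: float, indel_rate: float, rng) -> str:
    out = []
    for c in planted:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(_BASES[rng.integers(4)])  # insertion before base
        if rng.random() < sub_rate:
            c = _BASES[(_BASES.index(c) + 1 + rng.integers(3)) % 4]
        out.append(c)
    return "".join(out)


def simulate_marker_sequences(
    params: InsertionSimParams,
) -> list[tuple[MarkerRecord, dict]]:
    """Generate marker sequences with planted repeats and truth records.

    The microsatellite (tiled ``micro_unit``, length ``micro_length``) is
    planted unmutated in the middle of ITS1; the minisatellite —
    ⌊copies⌋ full copies plus a prefix of ⌊(copies−⌊copies⌋)·period⌋
    bases — is planted in ITS2 and then mutated at the stated per-base
    rates.  Two junction-guard bases on each side of each planted array
    prevent accidental extension into the backbone.  Truth intervals are
    0-based half-open in the final sequence.
    """
    rng = np.random.default_rng(params.seed)
    period = len(params.minis_consensus)
    full = int(params.minis_copies)
    # epsilon-guarded floor: 2.8 copies of an 80-mer is exactly 224 bp
    prefix = int(math.floor(params.minis_copies * period + 1e-9)) - full * period
    planted_mini = params.minis_consensus * full + params.minis_consensus[:prefix]
    micro_run = (params.micro_unit * params.micro_length)[: params.micro_length]
    out = []
    for i in range(params.n_sequences):
        backbone = list(
            "".join(_BASES[b] for b in rng.integers(0, 4, params.backbone_length))
        )
        ann = dict(params.its_annotation)

        # --- ITS1 microsatellite (planted pure)
        s1, e1 = ann["ITS1"]
        if params.micro_length:
            if e1 - s1 < params.micro_length + 4:
                raise ValueError("ITS1 interval too short for the microsatellite")
            mstart = s1 + (e1 - s1 - params.micro_length) // 2
            mend = mstart + params.micro_length
            backbone[mstart:mend] = micro_run
            unit = params.micro_unit
            backbone[mstart - 1] = _guard_base(unit[-1])
            backbone[mstart - 2] = _guard_base(unit[-2 % len(unit)])
            backbone[mend] = _guard_base(unit[0])
            backbone[mend + 1] = _guard_base(unit[1 % len(unit)])
            micro_truth = (mstart, mend)
        else:
            micro_truth = None

        # --- ITS2 minisatellite (planted, then mutated)
        s2, e2 = ann["ITS2"]
        mutated = _mutate(
            planted_mini, params.minis_sub_rate, params.minis_indel_rate, rng
        )
        if e2 - s2 < len(mutated) + 4:
            raise ValueError("ITS2 interval too short for the minisatellite")
        istart = s2 + (e2 - s2 - len(mutated)) // 2
        iend = istart + len(mutated)
        backbone[istart:iend] = mutated
        cons = params.minis_consensus
        backbone[istart - 1] = _guard_base(cons[-1])
        backbone[istart - 2] = _guard_base(cons[-2 % period])
        backbone[iend] = _guard_base(cons[prefix % period])
        backbone[iend + 1] = _guard_base(cons[(prefix + 1) % period])

        record = MarkerRecord(
            seq_id=f"sim{i:03d}",
            sequence="".join(backbone),
            annotation=ann,
        )
        truth = {
            "micro": micro_truth,
            "micro_unit": params.micro_unit,
            "mini": (istart, iend),
            "mini_consensus": cons,
            "mini_copies": params.minis_copies,
            "mini_planted": planted_mini,
            "mini_planted_length": len(planted_mini),
        }
        out.append((record, truth))
    return out


# ---------------------------------------------------------------------------
# spore measurements


@dataclass
class SporeSimParams:
    """Bivariate-Gaussian spore measurement design (μm).

    Defaults emulate a 19-collection survey measuring 31 spores per
    collection with means (11.6, 5.0) μm.
    """

    mean_length: float = 11.6
    mean_width: float = 5.0
    cov: tuple = ((0.36, 0.0), (0.0, 0.04))
    between_collection_sd: float = 0.3
    n_per_collection: int = 31
    m_basidiomes: int = 1
    p_collections: int = 19
    structure: str = "basidiospores"
    seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2) or not np.allclose(c, c.T):
            raise ValueError("cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(c).min() < -1e-12:
            raise ValueError("cov must be positive semi-definite")
        if min(self.n_per_collection, self.m_basidiomes, self.p_collections) < 1:
            raise ValueError("all counts must be >= 1")
        if self.mean_length <= 0 or self.mean_width <= 0:
            raise ValueError("means must be positive")


def simulate_spore_measurements(params: SporeSimParams) -> MeasurementSet:
    """Draw (length, width) pairs per collection around jittered means.

    Draws with a non-positive dimension are redrawn (truncation by
    rejection, keeping the Gaussian shape in the bulk).
    """
    rng = np.random.default_rng(params.seed)
    cov = np.asarray(params.cov, dtype=float)
    mean = np.array([params.mean_length, params.mean_width])
    rows = []
    for ci in range(params.p_collections):
        cmean = mean + rng.normal(0.0, params.between_collection_sd, size=2)
        per_bas = np.array_split(
            np.arange(params.n_per_collection), params.m_basidiomes
        )
        for bi, idx in enumerate(per_bas):
            for _ in idx:
                while True:
                    l, w = rng.multivariate_normal(cmean, cov, method="svd")
                    if l > 0 and w > 0:
                        break
                rows.append(
                    {
                        "collection": f"C{ci + 1:03d}",
                        "basidiome": f"C{ci + 1:03d}-B{bi + 1:02d}",
                        "structure": params.structure,
                        "length_um": l,
                        "width_um": w,
                    }
                )
    return MeasurementSet(
        structure=params.structure, data=pd.DataFrame(rows)
    )
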