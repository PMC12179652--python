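"""Readers/writers for the formats the pipeline touches, plus reports.

Formats: FASTA (80-column wrap), BED-like 4-column annotation
(seqid, start 0-based, end half-open, region), Newick with "BS/PP"
internal labels, measurement CSV (collection,basidiome,structure,
length_um,width_um), and tab-separated report tables.  Reports print
1-based inclusive coordinates; every report starts with a header line
recording the package version, a config hash and the seed, so equal
configurations produce byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .gcpsr import DelimitationResult, Genealogy, parse_annotated_tree
from .morphometrics import Ellipse, MeasurementSet, SummaryStats
from .tandem_repeats import MarkerRecord, RepeatHit, SpeciesInsertionProfile

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "read_measurements",
    "write_measurements",
    "read_locus_manifest",
    "load_genealogies",
    "render_reports",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; hashed into report headers."""

    subcommand: str = ""
    inputs: tuple[str, ...] = ()
    weights: str = "2-7-7"
    second_pass: str | None = None
    support_convention: str = "bs/pp"
    level: float = 0.68
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def header(self) -> str:
        return (
            f"# boletax {__version__}\tconfig={self.config_hash()}"
            f"\tseed={self.seed}"
        )


def read_fasta(path) -> list[MarkerRecord]:
    """Read marker sequences; sequences are uppercased and the non-ATGC
    fraction recomputed on load.  Duplicate ids or an empty file error."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(MarkerRecord(seq_id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[MarkerRecord], path, wrap: int = 80) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.seq_id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqs)


def read_annotation(path) -> dict[str, dict[str, tuple[int, int]]]:
    """Read 4-column BED-like annotation: seqid, start, end, region."""
    out: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields")
            seqid, start, end, region = parts
            out.setdefault(seqid, {})[region] = (int(start), int(end))
    return out


def write_annotation(ann: Mapping[str, Mapping[str, tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for seqid in sorted(ann):
            for region in ("ITS1", "5.8S", "ITS2"):
                if region in ann[seqid]:
                    s, e = ann[seqid][region]
                    fh.write(f"{seqid}\t{s}\t{e}\t{region}\n")


def attach_annotation(records: Sequence[MarkerRecord], ann) -> None:
    for r in records:
        if r.seq_id in ann:
            r.annotation = dict(ann[r.seq_id])


_CSV_COLS = ["collection", "basidiome", "structure", "length_um", "width_um"]


def read_measurements(path) -> dict[str, MeasurementSet]:
    """Read a measurement CSV; returns one MeasurementSet per structure."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {
        structure: MeasurementSet(structure=structure, data=g.reset_index(drop=True))
        for structure, g in df.groupby("structure")
    }


def write_measurements(ms: MeasurementSet, path) -> None:
    ms.data[_CSV_COLS].to_csv(path, index=False, float_format="%.3f")


def read_locus_manifest(path) -> list[dict]:
    """Tab-separated manifest: locus, linkage_group, tree_path,
    support_convention (paths relative to the manifest)."""
    base = Path(path).parent
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields")
            locus, group, tree_path, convention = parts
            rows.append(
                {
                    "locus": locus,
                    "linkage_group": group,
                    "tree_path": str((base / tree_path)),
                    "support_convention": convention,
                }
            )
    if not rows:
        raise ValueError(f"empty locus manifest {path}")
    return rows


def load_genealogies(manifest_path, outgroup: str) -> list[Genealogy]:
    out = []
    for row in read_locus_manifest(manifest_path):
        newick = Path(row["tree_path"]).read_text()
        out.append(
            parse_annotated_tree(
                newick,
                locus=row["locus"],
                linkage_group=row["linkage_group"],
                support_convention=row["support_convention"],
                outgroup=outgroup,
            )
        )
    return out


# ---------------------------------------------------------------------------
# report rendering


def _fmt_range(rng, nd=0) -> str:
    if rng is None:
        return "ND"
    lo, hi = rng
    f = f"{{:.{nd}f}}"
    return f.format(lo) if lo == hi else f"{f.format(lo)}–{f.format(hi)}"


def _write_hit_table(hits: Sequence[RepeatHit], path, header: str) -> None:
    cols = [
        "seq_id", "start", "end", "period", "copy_number",
        "consensus_size", "percent_matches", "percent_indels", "score",
        "consensus",
    ]
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write("\t".join(cols) + "\n")
        for h in sorted(hits, key=lambda h: (h.seq_id, h.start)):
            fh.write(
                f"{h.seq_id}\t{h.start + 1}\t{h.end}\t{h.period}\t"
                f"{h.copy_number:.1f}\t{len(h.consensus)}\t"
                f"{h.percent_matches}\t{h.percent_indels}\t{h.score}\t"
                f"{h.consensus}\n"
            )


def _write_profile_table(
    profiles: Sequence[SpeciesInsertionProfile], path, header: str
) -> None:
    cols = [
        "species", "region", "n_sequences", "its_length", "insertion_size",
        "weights", "consensus_patterns", "copy_number", "percent_matches",
        "percent_indels", "similarity",
    ]
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write("\t".join(cols) + "\n")
        for p in profiles:
            patterns = (
                "; ".join(f"{c} ({len(c)})" for c in p.consensus_patterns)
                if p.consensus_patterns
                else "ND"
            )
            fh.write(
                "\t".join(
                    [
                        p.species,
                        p.region,
                        str(p.n_sequences),
                        _fmt_range(p.its_length_range),
                        _fmt_range(p.insertion_size_range),
                        p.weights,
                        patterns,
                        _fmt_range(p.copy_number_range, 1),
                        _fmt_range(p.percent_matches_range),
                        _fmt_range(p.percent_indels_range),
                        _fmt_range(p.similarity_range, 1),
                    ]
                )
                + "\n"
            )


def _write_delimitation_report(
    result: DelimitationResult, path, header: str
) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write("lineage\tstatus\ttaxa\tsupporting_loci\tlinkage_groups\tflags\n")
        for i, l in enumerate(result.lineages, 1):
            fh.write(
                f"L{i:03d}\t{l.status}\t{','.join(sorted(l.taxa))}\t"
                f"{','.join(l.supporting_loci)}\t{','.join(l.linkage_groups)}\t"
                f"{','.join(l.flags) or '-'}\n"
            )
        fh.write("\n# Putative lineages (single linkage group; review whether\n")
        fh.write("# non-overlapping putative lineages may be conspecific)\n")
        for i, l in enumerate(result.lineages, 1):
            if l.status == "putative_species":
                fh.write(f"# L{i:03d}\t{','.join(sorted(l.taxa))}\n")
        fh.write(f"\n# Unassigned taxa: {','.join(result.unassigned) or '-'}\n")
        np_ = len(result.phylogenetic_species)
        nq = len(result.putative_species)
        fh.write(
            f"# Summary: {np_} phylogenetic species, {nq} putative species, "
            f"{len(result.unassigned)} unassigned taxa\n"
        )


def _write_morpho_report(payload: dict, path, header: str) -> None:
    stats: SummaryStats = payload["stats"]
    text: str = payload["text"]
    ellipse: Ellipse | None = payload.get("ellipse")
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write(f"structure\t{payload['structure']}\n")
        fh.write(f"summary\t{text}\n")
        for name, block in (
            ("length_um", stats.length), ("width_um", stats.width),
            ("Q", stats.q), ("Vm_um3", stats.vm),
        ):
            fh.write(
                f"{name}\tmin={block.min:.4f}\tmean={block.mean:.4f}\t"
                f"sd={block.sd:.4f}\tmax={block.max:.4f}\n"
            )
        if ellipse is not None:
            fh.write(
                f"ellipse\tcenter=({ellipse.center[0]:.4f},{ellipse.center[1]:.4f})"
                f"\tsemi_axes=({ellipse.semi_axes[0]:.4f},{ellipse.semi_axes[1]:.4f})"
                f"\tangle_rad={ellipse.angle:.4f}\tlevel={ellipse.level}\n"
            )


def render_reports(results: Mapping[str, object], out_dir, config: RunConfig) -> list[Path]:
    """Write one tab-separated report per result kind.

    Recognised keys: ``hits`` (list of RepeatHit), ``hits_pass2``,
    ``profiles`` (list of SpeciesInsertionProfile), ``delimitation``
    (DelimitationResult), ``morphometrics`` (dict with stats/text/
    ellipse).  Deterministic byte output for equal inputs and config.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}")
    header = config.header()
    written = []
    dispatch = {
        "hits": ("repeat_hits.tsv", _write_hit_table),
        "hits_pass2": ("repeat_hits_pass2.tsv", _write_hit_table),
        "profiles": ("insertion_profiles.tsv", _write_profile_table),
        "delimitation": ("delimitation.tsv", _write_delimitation_report),
        "morphometrics": ("morphometrics.tsv", _write_morpho_report),
    }
    for key, payload in results.items():
        if key not in dispatch:
            raise ValueError(f"unknown result kind {key!r}")
        fname, writer = dispatch[key]
        path = out / fname
        writer(payload, path, header)
        written.append(path)
    return written
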