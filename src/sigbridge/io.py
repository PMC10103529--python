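"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: NanoString RCC lane files (sectioned ``<Tag>``/``</Tag>``
text with a CSV ``Code_Summary``), GMT gene-set files, TSV count matrices
with a probe-class sidecar, sample-metadata TSV, and a 3-column gene alias
map used to reconcile whole-transcriptome gene names with panel probe names.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .containers import CountMatrix, SignatureCollection

log = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "patient_id", "response", "treatment",
                    "biopsy_site", "batch"]


class FormatError(ValueError):
    """A file does not conform to its declared plain-text format."""


# ---------------------------------------------------------------------------
# RCC lane files
# ---------------------------------------------------------------------------

@dataclass
class RccLane:
    """One NanoString lane: probe records plus the file's attribute sections."""

    probes: pd.DataFrame  # columns: code_class, name, accession, count
    header: dict[str, str] = field(default_factory=dict)
    sample_attributes: dict[str, str] = field(default_factory=dict)
    lane_attributes: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> pd.Series:
        return self.probes.set_index("name")["count"]


def _parse_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("</") and line.endswith(">"):
            current = None
        elif line.startswith("<") and line.endswith(">"):
            current = line[1:-1]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return sections


def read_rcc(path) -> RccLane:
    """Parse one RCC lane file.

    Requires a ``Code_Summary`` section whose rows are
    ``CodeClass,Name,Accession,Count``; counts must be integers and probe
    names unique within the lane.
    """
    path = Path(path)
    sections = _parse_sections(path.read_text())
    if "Code_Summary" not in sections:
        raise FormatError(f"{path}: missing Code_Summary section")

    def kv(name: str) -> dict[str, str]:
        out = {}
        for line in sections.get(name, []):
            key, _, value = line.partition(",")
            out[key] = value
        return out

    rows = []
    body = sections["Code_Summary"]
    if body and body[0].lower().startswith("codeclass"):
        body = body[1:]
    for i, line in enumerate(body, start=1):
        parts = line.split(",")
        if len(parts) != 4:
            raise FormatError(f"{path}: Code_Summary row {i} has "
                              f"{len(parts)} fields, expected 4")
        klass, name, accession, count = (p.strip() for p in parts)
        try:
            n = int(count)
        except ValueError:
            raise FormatError(f"{path}: non-integer count {count!r} at "
                              f"Code_Summary row {i}") from None
        if n < 0:
            raise FormatError(f"{path}: negative count at Code_Summary row {i}")
        rows.append((klass, name, accession, n))
    probes = pd.DataFrame(rows, columns=["code_class", "name", "accession", "count"])
    if probes.empty:
        log.warning("%s: empty Code_Summary", path)
    dupes = probes["name"][probes["name"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicated probe name(s): {list(dupes)}")
    return RccLane(probes, header=kv("Header"),
                   sample_attributes=kv("Sample_Attributes"),
                   lane_attributes=kv("Lane_Attributes"))


def write_rcc(lane: RccLane, path) -> None:
    """Write an :class:`RccLane` back to the sectioned RCC text format."""
    parts = []
    for tag, attrs in [("Header", lane.header),
                       ("Sample_Attributes", lane.sample_attributes),
                       ("Lane_Attributes", lane.lane_attributes)]:
        parts.append(f"<{tag}>")
        parts.extend(f"{k},{v}" for k, v in attrs.items())
        parts.append(f"</{tag}>")
    parts.append("<Code_Summary>")
    parts.append("CodeClass,Name,Accession,Count")
    for rec in lane.probes.itertuples(index=False):
        parts.append(f"{rec.code_class},{rec.name},{rec.accession},{rec.count}")
    parts.append("</Code_Summary>")
    Path(path).write_text("\n".join(parts) + "\n")


def rcc_dir_to_matrix(paths, platform: str = "panel") -> CountMatrix:
    """Assemble lane files into one CountMatrix (sample id = lane ID attr
    or file stem)."""
    cols, classes = {}, None
    for p in paths:
        lane = read_rcc(p)
        sid = lane.lane_attributes.get("ID") or Path(p).stem
        cols[sid] = lane.counts
        classes = lane.probes.set_index("name")["code_class"]
    counts = pd.DataFrame(cols).fillna(0).astype(int)
    return CountMatrix(counts, classes, platform)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> SignatureCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    coll = SignatureCollection()
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {i} has fewer than 3 fields")
        name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
        if not members:
            raise FormatError(f"{path}: signature {name!r} has no members")
        coll.add(name, members, desc)
    return coll


def write_gmt(collection: SignatureCollection, path) -> None:
    lines = []
    for name, members in collection.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices, metadata, alias maps
# ---------------------------------------------------------------------------

def read_counts(path, classes_path=None, platform: str = "") -> CountMatrix:
    """Read a genes-as-rows TSV count matrix, optionally with a 2-column
    probe-class sidecar TSV (gene, code_class)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    classes = None
    if classes_path is not None:
        side = pd.read_csv(classes_path, sep="\t", index_col=0)
        classes = side.iloc[:, 0]
    return CountMatrix(counts, classes, platform)


def write_counts(matrix: CountMatrix, path, classes_path=None) -> None:
    matrix.counts.to_csv(path, sep="\t")
    if classes_path is not None and matrix.code_class is not None:
        matrix.code_class.rename("code_class").to_csv(classes_path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing required columns {missing}")
    return meta


@dataclass
class AliasMap:
    """Gene-name reconciliation actions.

    Each row maps one or more source gene names to a target probe name with
    an action: ``rename`` (one source relabelled), ``merge`` (several source
    rows combined into one target row) or ``drop`` (panel probe with no
    transcriptome match, removed from the overlap).
    """

    rows: list[tuple[tuple[str, ...], str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        targets = [t for _, t, a in self.rows if a == "merge"]
        dupes = {t for t in targets if targets.count(t) > 1}
        if dupes:
            raise ValueError(f"target(s) in more than one merge group: {sorted(dupes)}")
        for srcs, tgt, action in self.rows:
            if action not in ("rename", "merge", "drop"):
                raise ValueError(f"unknown alias action {action!r}")
            if action == "rename" and len(srcs) != 1:
                raise ValueError(f"rename of {tgt!r} must have exactly one source")


def read_alias_map(path) -> AliasMap:
    """Read a 3-column TSV: source gene(s) (comma separated), target, action."""
    rows = []
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: line {i} must have 3 tab-separated fields")
        srcs = tuple(s.strip() for s in parts[0].split(",") if s.strip())
        rows.append((srcs, parts[1].strip(), parts[2].strip()))
    return AliasMap(rows)


def reconcile_genes(wts: CountMatrix, panel_genes, alias_map: AliasMap | None = None,
                    restrict_to_overlap: bool = False):
    """Reconcile whole-transcriptome gene names against panel probe names.

    Merge groups are combined into a single row by summing counts (the rule
    that conserves total reads), renames relabel rows, and panel probes with
    no transcriptome match after alias application are reported as dropped.

    Returns ``(matrix, report)`` where the report lists renames, merges, the
    dropped panel probes, the final overlap, and the merge rule applied.
    Matching is case-sensitive exact string equality.
    """
    counts = wts.counts.copy()
    report = {"renamed": {}, "merged": {}, "dropped_panel": [],
              "merge_rule": "sum"}
    for srcs, target, action in (alias_map.rows if alias_map else []):
        if action == "drop":
            report["dropped_panel"].append(target)
            continue
        missing = [g for g in srcs if g not in counts.index]
        if missing:
            raise KeyError(f"alias sources absent from matrix: {missing} "
                           f"(target {target!r})")
        if action == "rename":
            counts = counts.rename(index={srcs[0]: target})
            report["renamed"][srcs[0]] = target
        else:  # merge
            merged = counts.loc[list(srcs)].sum(axis=0)
            counts = counts.drop(index=list(srcs))
            counts.loc[target] = merged
            report["merged"][target] = list(srcs)
    panel_genes = list(panel_genes)
    overlap = [g for g in panel_genes if g in counts.index]
    unmatched = sorted(set(panel_genes) - set(overlap) - set(report["dropped_panel"]))
    report["dropped_panel"].extend(unmatched)
    report["overlap"] = overlap
    if restrict_to_overlap:
        counts = counts.loc[overlap]
    out = CountMatrix(counts, None, wts.platform)
    return out, report


def restrict_signatures(collection: SignatureCollection, universe):
    """Keep only the signatures fully contained in ``universe``.

    Returns ``(kept, excluded)`` where ``excluded`` maps each dropped
    signature name to its missing genes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    kept = SignatureCollection()
    excluded: dict[str, list[str]] = {}
    for name, members in collection.items():
        missing = [g for g in members if g not in universe]
        if missing:
            excluded[name] = missing
        else:
            kept.add(name, members, collection.descriptions.get(name, ""))
    return kept, excluded
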