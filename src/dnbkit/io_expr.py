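"""Readers/writers for expression tables, gene networks, pathway sets, and results.

All formats are plain text: delimited expression matrices with a sample
metadata table, two-column TSV or SIF edge lists, GMT gene sets, and TSV
result tables. Gene identifiers are matched exactly (case-sensitive)
everywhere; non-overlapping identifiers between inputs are reported, never
silently folded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from dnbkit.dnb_core import DNBResult

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """An input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSeries:
    """A genes x samples expression matrix with timepoint/replicate metadata.

    Parameters
    ----------
    genes
        Ordered unique gene identifiers (rows of ``values``).
    samples
        Ordered unique sample identifiers (columns of ``values``).
    values
        Numeric matrix of shape ``(len(genes), len(samples))``. No missing
        values are permitted; the loaders enforce this.
    timepoint_of
        Map sample -> timepoint label. Every sample must be assigned.
    replicate_of
        Map sample -> replicate index within its timepoint.
    timepoint_order
        The declared total order of timepoint labels.
    scale
        ``"raw"`` or ``"log"`` -- the user-declared scale of ``values``.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    timepoint_of: dict[str, str]
    replicate_of: dict[str, int]
    timepoint_order: list[str]
    scale: str = "raw"
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        missing = [s for s in self.samples if s not in self.timepoint_of]
        if missing:
            raise ValueError(f"samples without a timepoint label: {missing}")
        used = {self.timepoint_of[s] for s in self.samples}
        if not used <= set(self.timepoint_order):
            raise ValueError(
                f"timepoints missing from declared order: {sorted(used - set(self.timepoint_order))}"
            )
        if len(set(self.timepoint_order)) != len(self.timepoint_order):
            raise ValueError("timepoint_order contains duplicates")
        # drop declared-but-unused timepoints so each retained timepoint has >=1 sample
        self.timepoint_order = [t for t in self.timepoint_order if t in used]
        if self.scale not in ("raw", "log"):
            raise ValueError(f"scale must be 'raw' or 'log', got {self.scale!r}")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    # -- accessors -----------------------------------------------------------

    @property
    def timepoints(self) -> list[str]:
        return list(self.timepoint_order)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def samples_at(self, timepoint: str) -> list[str]:
        if timepoint not in self.timepoint_order:
            raise KeyError(f"unknown timepoint {timepoint!r}")
        return [s for s in self.samples if self.timepoint_of[s] == timepoint]

    def n_replicates(self, timepoint: str) -> int:
        return len(self.samples_at(timepoint))

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._gene_index[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in series") from None

    def replicate_matrix(self, timepoint: str, genes: Sequence[str] | None = None) -> np.ndarray:
        """Sub-matrix ``genes x replicates`` for one timepoint."""
        cols = [self.samples.index(s) for s in self.samples_at(timepoint)]
        rows = slice(None) if genes is None else self.gene_indices(genes)
        return self.values[rows][:, cols]

    def order_genes(self, genes: Iterable[str]) -> list[str]:
        """Return ``genes`` sorted by their row order in the series."""
        return sorted(genes, key=lambda g: self._gene_index[g])


@dataclass
class GeneNetwork:
    """Undirected gene-gene network: no self-loops, no duplicate edges."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"network contains self-loops: {loops[:5]}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "GeneNetwork":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class PathwayCollection:
    """Named gene sets plus the declared reference-count used for normalization."""

    pathways: dict[str, set[str]]
    total_reference_count: int

    def __post_init__(self) -> None:
        if self.total_reference_count < 1:
            raise ValueError("total_reference_count must be >= 1")
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")
        if self.total_reference_count < len(self.pathways):
            log.warning(
                "total_reference_count (%d) is below the number of loaded pathways (%d)",
                self.total_reference_count,
                len(self.pathways),
            )

    def hits(self, gene: str) -> int:
        return sum(gene in genes for genes in self.pathways.values())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_table(
    matrix_path: str | Path,
    metadata_path: str | Path,
    scale: str = "raw",
    delimiter: str | None = None,
    missing: str = "error",
) -> ExpressionSeries:
    """Load an expression matrix plus its sample metadata.

    The matrix is delimited text: first column gene IDs, header row sample
    IDs. The metadata table has columns ``sample``, ``timepoint``,
    ``replicate``; the order of first appearance of timepoint labels defines
    their total order.

    ``missing`` is ``"error"`` (default) or ``"drop"`` (drop genes with any
    missing value, reporting the count). Values are never imputed.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    if missing not in ("error", "drop"):
        raise ValueError("missing policy must be 'error' or 'drop'")

    raw = pd.read_csv(
        matrix_path,
        sep=_sep_for(matrix_path, delimiter),
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    dup = raw.index[raw.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{matrix_path}: duplicate gene identifiers: {dup}")

    stripped = raw.apply(lambda col: col.str.strip())
    empty = stripped == ""
    numeric = stripped.mask(empty).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~empty
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{matrix_path}: non-numeric value {raw.iat[gi, si]!r} at "
            f"gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    if empty.to_numpy().any():
        n_bad_genes = int(empty.any(axis=1).sum())
        if missing == "error":
            gi, si = np.argwhere(empty.to_numpy())[0]
            raise FormatError(
                f"{matrix_path}: missing value at gene {raw.index[gi]!r}, "
                f"sample {raw.columns[si]!r} (use missing='drop' to drop such genes)"
            )
        numeric = numeric.loc[~empty.any(axis=1)]
        log.warning("dropped %d gene(s) with missing values", n_bad_genes)

    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path, delimiter), dtype=str)
    required = {"sample", "timepoint", "replicate"}
    if not required <= set(meta.columns):
        raise FormatError(
            f"{metadata_path}: metadata must have columns {sorted(required)}, "
            f"found {list(meta.columns)}"
        )
    meta_samples = set(meta["sample"])
    unknown = [s for s in numeric.columns if s not in meta_samples]
    if unknown:
        raise FormatError(f"{metadata_path}: samples missing from metadata: {unknown}")
    extra = sorted(meta_samples - set(numeric.columns))
    if extra:
        log.info("metadata rows for %d sample(s) absent from the matrix are ignored", len(extra))

    timepoint_of = dict(zip(meta["sample"], meta["timepoint"]))
    replicate_of = {s: int(r) for s, r in zip(meta["sample"], meta["replicate"])}
    order = list(dict.fromkeys(meta["timepoint"]))

    return ExpressionSeries(
        genes=numeric.index.tolist(),
        samples=numeric.columns.tolist(),
        values=numeric.to_numpy(dtype=float),
        timepoint_of={s: timepoint_of[s] for s in numeric.columns},
        replicate_of={s: replicate_of[s] for s in numeric.columns},
        timepoint_order=order,
        scale=scale,
    )


def write_expression_table(
    series: ExpressionSeries,
    matrix_path: str | Path,
    metadata_path: str | Path,
    delimiter: str | None = None,
) -> None:
    """Write a series back to matrix + metadata text files (full precision)."""
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    sep = _sep_for(matrix_path, delimiter)
    with open(matrix_path, "w") as fh:
        fh.write("gene" + sep + sep.join(series.samples) + "\n")
        for g, row in zip(series.genes, series.values):
            fh.write(g + sep + sep.join(repr(float(v)) for v in row) + "\n")
    msep = _sep_for(metadata_path, delimiter)
    with open(metadata_path, "w") as fh:
        fh.write(msep.join(["sample", "timepoint", "replicate"]) + "\n")
        for s in series.samples:
            fh.write(msep.join([s, series.timepoint_of[s], str(series.replicate_of[s])]) + "\n")


def read_gmt(path: str | Path, total_reference_count: int | None = None) -> PathwayCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>gene1<TAB>...``.

    ``total_reference_count`` defaults to the number of pathway lines; pass
    e.g. 185 to normalize against a larger declared reference collection.
    """
    path = Path(path)
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(parts)}"
                )
            name = parts[0]
            genes = {g.strip() for g in parts[2:] if g.strip()}
            if not genes:
                raise FormatError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            if name in pathways:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            pathways[name] = genes
    total = len(pathways) if total_reference_count is None else total_reference_count
    return PathwayCollection(pathways=pathways, total_reference_count=total)


def read_network_edges(path: str | Path) -> GeneNetwork:
    """Parse a 2-column TSV or SIF edge list into an undirected network.

    SIF lines (``source<TAB>interaction<TAB>target [target ...]``) may list
    several targets. Duplicate edges (in either orientation) are collapsed;
    self-loops are dropped with a logged count.
    """
    path = Path(path)
    graph = nx.Graph()
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) == 2:
                pairs = [(fields[0], fields[1])]
            elif len(fields) >= 3:
                pairs = [(fields[0], t) for t in fields[2:] if t.strip()]
            else:
                raise FormatError(f"{path}: line {lineno}: malformed edge line {line.rstrip()!r}")
            for a, b in pairs:
                if not a.strip() or not b.strip():
                    raise FormatError(f"{path}: line {lineno}: empty node identifier")
                if a == b:
                    dropped += 1
                    continue
                graph.add_edge(a, b)
    if dropped:
        log.info("dropped %d self-loop(s) while reading %s", dropped, path)
    return GeneNetwork(graph=graph)


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

_PROFILE_HEADER = ["timepoint", "size", "SD_in", "PCC_in", "PCC_out", "CI"]
_MEMBERS_HEADER = ["gene", "index_one", "index_two", "integrated_index", "rank"]


def _fmt(x: float) -> str:
    return f"{float(x):.12g}"


def write_results(
    result: "DNBResult",
    out_dir: str | Path,
    run_config: Mapping | None = None,
) -> dict[str, Path]:
    """Write ``criticality_profile.tsv``, ``dnb_members.tsv`` and a config echo.

    Output is deterministic: fixed column order, profile rows in timepoint
    order, member rows in ascending rank (or gene order when the result
    carries no ranking).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    profile_path = out_dir / "criticality_profile.tsv"
    with open(profile_path, "w") as fh:
        fh.write("\t".join(_PROFILE_HEADER) + "\n")
        prof = result.profile
        if prof is not None:
            for i, tp in enumerate(prof.timepoints):
                fh.write(
                    "\t".join(
                        [
                            tp,
                            str(prof.size),
                            _fmt(prof.sd_in[i]),
                            _fmt(prof.pcc_in[i]),
                            _fmt(prof.pcc_out[i]),
                            _fmt(prof.ci[i]),
                        ]
                    )
                    + "\n"
                )

    members_path = out_dir / "dnb_members.tsv"
    with open(members_path, "w") as fh:
        fh.write("\t".join(_MEMBERS_HEADER) + "\n")
        if result.members is not None:
            for m in sorted(result.members, key=lambda m: m.rank):
                fh.write(
                    "\t".join(
                        [m.gene, _fmt(m.index_one), _fmt(m.index_two), _fmt(m.integrated_index), str(m.rank)]
                    )
                    + "\n"
                )
        else:
            for i, g in enumerate(sorted(result.group), 1):
                fh.write("\t".join([g, "NA", "NA", "NA", str(i)]) + "\n")

    config_path = out_dir / "run_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(dict(run_config or {}), fh, sort_keys=True)

    return {"profile": profile_path, "members": members_path, "config": config_path}
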