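"""Reading, validation, filtering and sample alignment of the omics matrices.

Three gene x sample matrices enter the pipeline: continuous expression
(RPKM-like), methylation beta-values in [0, 1], and discrete gene-level
copy-number calls in {-2, -1, 0, 1, 2}.  A two-column design table assigns
each sample to the ``tumor`` or ``normal`` group.  Matrices are plain
tab-separated text: first column gene symbol, header row of sample ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("icds")

LAYER_KINDS = ("expression", "methylation", "cnv")
GROUP_LABELS = ("tumor", "normal")
_CNV_CALLS = frozenset((-2.0, -1.0, 0.0, 1.0, 2.0))


@dataclass(frozen=True)
class SampleDesign:
    """Tumor/normal group assignment; the single source of group labels."""

    samples: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self):
        if len(self.samples) != len(self.groups):
            raise ValidationError("design: samples and groups differ in length")
        if len(set(self.samples)) != len(self.samples):
            dupes = pd.Index(self.samples)
            raise ValidationError(
                "design: duplicate sample ids: "
                + ", ".join(sorted(dupes[dupes.duplicated()].unique()))
            )
        bad = sorted({g for g in self.groups if g not in GROUP_LABELS})
        if bad:
            raise ValidationError(f"design: unknown group labels {bad}; expected {GROUP_LABELS}")

    @property
    def group_of(self) -> dict[str, str]:
        return dict(zip(self.samples, self.groups))

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in zip(self.samples, self.groups) if g == group)

    def subset(self, samples: Iterable[str]) -> "SampleDesign":
        keep = set(samples)
        pairs = [(s, g) for s, g in zip(self.samples, self.groups) if s in keep]
        return SampleDesign(tuple(s for s, _ in pairs), tuple(g for _, g in pairs))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SampleDesign":
        return cls(tuple(mapping), tuple(mapping.values()))


def read_design(path: str | Path) -> SampleDesign:
    """Read a two-column (sample_id, group) TSV; a header row is optional."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            rows.append((fields[0].strip(), fields[1].strip().lower()))
    if rows and rows[0][1] not in GROUP_LABELS:  # header row
        rows = rows[1:]
    if not rows:
        raise ValidationError(f"{path}: empty design file")
    return SampleDesign(tuple(r[0] for r in rows), tuple(r[1] for r in rows))


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in zip(design.samples, design.groups):
            fh.write(f"{s}\t{g}\n")


@dataclass
class OmicsLayer:
    """One gene x sample matrix plus its layer kind."""

    data: pd.DataFrame  # float values, index = gene symbols, columns = sample ids
    kind: str

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ValidationError(f"unknown layer kind {self.kind!r}; expected one of {LAYER_KINDS}")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def validate(self, source: str = "<matrix>") -> None:
        """Check layer-kind value invariants (NaN cells are always allowed)."""
        vals = self.data.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if self.kind == "methylation":
            bad = finite & ((vals < 0.0) | (vals > 1.0))
            if bad.any():
                gi, si = np.argwhere(bad)[0]
                raise ValidationError(
                    f"{source}: methylation value {vals[gi, si]!r} outside [0, 1] "
                    f"(gene {self.data.index[gi]!r}, sample {self.data.columns[si]!r})"
                )
        elif self.kind == "cnv":
            flat = vals[finite]
            bad = ~np.isin(flat, sorted(_CNV_CALLS))
            if bad.any():
                raise ValidationError(
                    f"{source}: cnv call {flat[bad][0]!r} not in {{-2,-1,0,1,2}}"
                )


def load_matrix(path: str | Path, kind: str) -> OmicsLayer:
    """Read a gene x sample TSV into a validated :class:`OmicsLayer`.

    Non-numeric cells become missing; duplicate gene rows are collapsed by
    their per-sample mean (logged).  Hard errors: empty file, no sample
    columns, duplicated sample ids in the header.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first.strip():
        raise ValidationError(f"{path}: empty file")
    header = first.split("\t")[1:]  # pandas mangles duplicate headers, so check here
    if not header:
        raise ValidationError(f"{path}: no sample columns in header")
    if len(set(header)) != len(header):
        counts = pd.Series(header).value_counts()
        dupes = sorted(counts[counts > 1].index)
        raise ValidationError(f"{path}: duplicated sample ids in header: {dupes}")
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, header=0)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    def _coerce(x) -> float:  # exact round-trip parse; non-numeric -> missing
        try:
            return float(x)
        except (TypeError, ValueError):
            return float("nan")

    values = raw.apply(lambda col: col.map(_coerce))
    values.index = values.index.astype(str)
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.info("%s: collapsed %d duplicate gene rows by mean", path.name, n_dup)
        values = values.groupby(level=0, sort=False).mean()
    layer = OmicsLayer(values.astype(float), kind)
    layer.validate(source=str(path))
    return layer


def write_matrix(layer: OmicsLayer, path: str | Path) -> None:
    """Write the layer back as TSV; values round-trip bit-exactly."""
    # repr() emits the shortest string that parses back to the same double
    layer.data.to_csv(path, sep="\t", index_label="gene",
                      float_format=lambda v: repr(float(v)))


def filter_low_coverage(layer: OmicsLayer, max_zero_frac: float = 0.8) -> OmicsLayer:
    """Drop genes whose fraction of zero-or-missing values strictly exceeds
    ``max_zero_frac``; gene order is otherwise preserved.

    Missing cells count as zeros here (and only here): level-3 exports use
    0 and NA interchangeably for absent signal.
    """
    vals = layer.data.to_numpy(dtype=float)
    zero_frac = ((vals == 0.0) | ~np.isfinite(vals)).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    if not keep.any():
        raise ValidationError(
            f"{layer.kind}: all {len(keep)} genes exceed the {max_zero_frac:.0%} "
            "zero fraction; review the threshold"
        )
    if (~keep).any():
        logger.info("%s: removed %d/%d genes with >%s zeros", layer.kind,
                    int((~keep).sum()), len(keep), max_zero_frac)
    return OmicsLayer(layer.data.loc[keep], layer.kind)


@dataclass
class AlignedOmics:
    """The three layers restricted to design samples, plus the gene universe.

    Layers need not share identical sample sets: each statistical test later
    uses the samples available in its own layer.  ``availability`` flags, per
    gene in the union, which layers carry that gene.
    """

    expression: OmicsLayer
    methylation: OmicsLayer
    cnv: OmicsLayer
    design: SampleDesign
    genes: tuple[str, ...] = field(default=())
    availability: pd.DataFrame | None = None

    def layer(self, kind: str) -> OmicsLayer:
        return {"expression": self.expression, "methylation": self.methylation,
                "cnv": self.cnv}[kind]


def align_layers(expr: OmicsLayer, methy: OmicsLayer, cnv: OmicsLayer,
                 design: SampleDesign) -> AlignedOmics:
    """Intersect each layer's samples with the design; union the genes."""
    aligned = []
    for layer in (expr, methy, cnv):
        keep = [s for s in layer.samples if s in set(design.samples)]
        if not keep:
            raise ValidationError(
                f"{layer.kind}: no samples shared with the design "
                f"({len(layer.samples)} layer samples, {len(design.samples)} design samples)"
            )
        aligned.append(OmicsLayer(layer.data.loc[:, keep], layer.kind))
    genes: list[str] = []
    seen: set[str] = set()
    for layer in aligned:
        for g in layer.genes:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    availability = pd.DataFrame(
        {l.kind: [g in set(l.genes) for g in genes] for l in aligned},
        index=pd.Index(genes, name="gene"),
    )
    return AlignedOmics(*aligned, design=design, genes=tuple(genes),
                        availability=availability)
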