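"""On-disk formats and validated in-memory domain types.

All matrices travel as features-in-rows, samples-in-columns TSV with
``feature_id`` as the first header cell.  Gene sets use the standard GMT
format.  Segment tables are SEG-like TSV with 1-based inclusive coordinates.
Missing numeric values are encoded as ``NA`` on disk and ``NaN`` in memory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("alclomics")

VALUE_KINDS = ("fpkm", "log2_expression", "beta", "m_value")
REGION_CLASSES = (
    "TSS",
    "five_prime_UTR",
    "first_exon",
    "gene_body",
    "three_prime_UTR",
    "intergenic",
)
TIMEPOINTS = ("diagnosis", "relapse")
HISTOLOGIES = ("common", "LH", "SCV", "unknown")
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")


class FormatError(ValueError):
    """A file does not conform to its documented layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """Feature x sample numeric matrix (expression FPKM, log2 expression,
    methylation beta or M-values)."""

    data: pd.DataFrame          # features x samples, float
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        finite = vals[np.isfinite(vals)]
        if self.value_kind == "fpkm" and finite.size and finite.min() < 0:
            f, s = self._locate(vals < 0)
            raise ValidationError(f"negative FPKM for feature {f!r}, sample {s!r}")
        if self.value_kind == "beta" and finite.size and (
                finite.min() < 0 or finite.max() > 1):
            f, s = self._locate((vals < 0) | (vals > 1))
            raise ValidationError(
                f"beta outside [0,1] for probe {f!r}, sample {s!r}")

    def _locate(self, mask: np.ndarray) -> tuple[str, str]:
        mask = mask & np.isfinite(self.data.to_numpy())
        i, j = np.argwhere(mask)[0]
        return str(self.data.index[i]), str(self.data.columns[j])

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, features=None, samples=None) -> "OmicsMatrix":
        df = self.data
        if features is not None:
            missing = set(features) - set(df.index)
            if missing:
                raise ValidationError(f"features absent from matrix: {sorted(missing)[:5]}")
            df = df.loc[list(features)]
        if samples is not None:
            missing = set(samples) - set(df.columns)
            if missing:
                raise ValidationError(f"samples absent from matrix: {sorted(missing)[:5]}")
            df = df[list(samples)]
        return OmicsMatrix(df.copy(), self.value_kind)


@dataclass
class ProbeManifest:
    """EPIC-style probe annotation: location, gene, region class, SNP VAF."""

    table: pd.DataFrame         # index probe_id

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "position", "gene", "region_class", "snp_vaf"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            raise FormatError("duplicate probe ids in manifest")
        bad = set(t["chrom"]) - set(CHROMOSOMES)
        if bad:
            raise ValidationError(f"unknown chromosomes: {sorted(bad)[:5]}")
        bad = set(t["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValidationError(f"unknown region classes: {sorted(bad)[:5]}")
        vaf = t["snp_vaf"].to_numpy(float)
        if np.any((vaf < 0) | (vaf > 1)):
            pid = t.index[np.argwhere((vaf < 0) | (vaf > 1))[0][0]]
            raise ValidationError(f"snp_vaf outside [0,1] for probe {pid!r}")

    @property
    def probe_ids(self) -> list[str]:
        return self.table.index.tolist()


@dataclass
class CohortMetadata:
    """Sample-level clinical annotations (timepoint, purity, survival, CN)."""

    table: pd.DataFrame         # index sample_id

    def __post_init__(self) -> None:
        t = self.table
        required = {"timepoint", "tumor_fraction", "survival_time", "event",
                    "histology", "cn_altered"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        bad = set(t["timepoint"]) - set(TIMEPOINTS)
        if bad:
            raise ValidationError(f"unknown timepoints: {sorted(bad)}")
        bad = set(t["histology"]) - set(HISTOLOGIES)
        if bad:
            raise ValidationError(f"unknown histologies: {sorted(bad)}")
        ev = t["event"].to_numpy(float)
        if not np.all(np.isin(ev[np.isfinite(ev)], (0.0, 1.0))):
            sid = t.index[np.argwhere(~np.isin(ev, (0.0, 1.0)))[0][0]]
            raise ValidationError(f"event not in {{0,1}} for sample {sid!r}")
        st = t["survival_time"].to_numpy(float)
        if np.any(st[np.isfinite(st)] < 0):
            sid = t.index[np.argwhere(st < 0)[0][0]]
            raise ValidationError(f"negative survival_time for sample {sid!r}")
        tf = t["tumor_fraction"].to_numpy(float)
        if np.any((tf[np.isfinite(tf)] < 0) | (tf[np.isfinite(tf)] > 1)):
            raise ValidationError("tumor_fraction outside [0,1]")
        bad = set(t["cn_altered"]) - {"true", "false", "unknown"}
        if bad:
            raise ValidationError(f"cn_altered must be true/false/unknown, got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()


@dataclass
class GeneSetLibrary:
    """Named gene sets with descriptions; gene lists deduplicated, order kept."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} not deduplicated")

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> list[str]:
        try:
            return self.sets[name][1]
        except KeyError:
            raise KeyError(f"unknown gene set {name!r}") from None


@dataclass
class SegmentTable:
    """Copy-number segments, 1-based inclusive coordinates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "chrom", "start", "end", "log2_ratio", "call"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"segment table missing columns: {sorted(missing)}")
        bad = set(t["call"]) - {"gain", "loss", "neutral"}
        if bad:
            raise ValidationError(f"unknown CN calls: {sorted(bad)}")
        s = t["start"].to_numpy(int)
        e = t["end"].to_numpy(int)
        if np.any(s > e):
            row = int(np.argwhere(s > e)[0][0])
            raise ValidationError(
                f"segment row {row}: start {s[row]} > end {e[row]}")


@dataclass
class MutationTable:
    """Somatic mutation calls (carrier type for plotting/integration)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "gene", "protein_change", "variant_class", "vaf"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"mutation table missing columns: {sorted(missing)}")
        vaf = t["vaf"].to_numpy(float)
        ok = np.isfinite(vaf)
        if np.any((vaf[ok] < 0) | (vaf[ok] > 1)):
            row = int(np.argwhere((vaf < 0) | (vaf > 1))[0][0])
            raise ValidationError(f"mutation row {row}: vaf {vaf[row]} outside [0,1]")


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def read_matrix(path, value_kind: str) -> OmicsMatrix:
    """Read a feature x sample TSV matrix; first column holds feature ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.name != "feature_id":
        raise FormatError(
            f"{path}: first header cell must be 'feature_id', got {df.index.name!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return OmicsMatrix(df, value_kind)
    except (FormatError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_matrix(matrix: OmicsMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_gmt(path) -> GeneSetLibrary:
    """Read a GMT gene-set library (name, description, genes...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc = parts[0], parts[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = (desc, genes)
    return GeneSetLibrary(sets)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in library.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _read_table(path, required: tuple[str, ...], index: str | None = None,
                dtypes: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    for col, typ in (dtypes or {}).items():
        df[col] = df[col].astype(typ)
    if index is not None:
        df = df.set_index(index)
        df.index = df.index.astype(str)
    return df


def read_metadata(path) -> CohortMetadata:
    df = _read_table(
        path,
        required=("sample_id", "timepoint", "tumor_fraction", "survival_time",
                  "event", "histology", "cn_altered"),
        index="sample_id",
        dtypes={"tumor_fraction": float, "survival_time": float, "event": float},
    )
    df["cn_altered"] = df["cn_altered"].fillna("unknown")
    df["histology"] = df["histology"].fillna("unknown")
    try:
        return CohortMetadata(df)
    except (FormatError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_metadata(metadata: CohortMetadata, path) -> None:
    df = metadata.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_manifest(path) -> ProbeManifest:
    df = _read_table(
        path,
        required=("probe_id", "chrom", "position", "gene", "region_class", "snp_vaf"),
        index="probe_id",
        dtypes={"position": int, "snp_vaf": float},
    )
    df["gene"] = df["gene"].fillna("")
    try:
        return ProbeManifest(df)
    except (FormatError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_manifest(manifest: ProbeManifest, path) -> None:
    df = manifest.table.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_segments(path) -> SegmentTable:
    df = _read_table(
        path,
        required=("sample_id", "chrom", "start", "end", "log2_ratio", "call"),
        dtypes={"start": int, "end": int, "log2_ratio": float},
    )
    try:
        return SegmentTable(df)
    except (FormatError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_segments(segments: SegmentTable, path) -> None:
    segments.table.to_csv(path, sep="\t", na_rep="NA", index=False)


def read_mutations(path) -> MutationTable:
    df = _read_table(
        path,
        required=("sample_id", "gene", "protein_change", "variant_class", "vaf"),
        dtypes={"vaf": float},
    )
    try:
        return MutationTable(df)
    except (FormatError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_mutations(mutations: MutationTable, path) -> None:
    mutations.table.to_csv(path, sep="\t", na_rep="NA", index=False)


def write_run_summary(path, stage: str, **info) -> None:
    """JSON run summary for a pipeline stage (shapes, filter counts, seed)."""
    payload = {"stage": stage, **info}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    log.info("stage=%s %s", stage,
             " ".join(f"{k}={v}" for k, v in info.items()))
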