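"""External representations: beta matrices, probe manifests, SEG segments,
sample sheets, Newick trees and JSON reports.

All coordinates are 1-based and inclusive, matching Illumina manifest and IGV
SEG practice; a probe occupies a single base position. Readers validate and
reject malformed input instead of repairing it, so that every downstream
module can assume the invariants documented on the container classes.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Gene-region annotation vocabulary of Illumina 450K/EPIC manifests.
GENE_REGION_CATEGORIES: tuple[str, ...] = (
    "TSS200", "TSS1500", "5UTR", "1stExon", "ExonBnd", "Body", "3UTR",
)
#: Label used for probes with an empty gene-region set (intergenic).
IGR: str = "IGR"
#: CpG-island relation partition. Orientation-carrying labels (N_Shore,
#: S_Shelf, ...) in input files are folded onto these four.
CGI_CATEGORIES: tuple[str, ...] = ("Island", "Shore", "Shelf", "OpenSea")

_CGI_FOLD = {
    "N_Shore": "Shore", "S_Shore": "Shore",
    "N_Shelf": "Shelf", "S_Shelf": "Shelf",
    "Island": "Island", "Shore": "Shore", "Shelf": "Shelf",
    "OpenSea": "OpenSea", "None": "OpenSea", "": "OpenSea",
}

SAMPLE_ROLES = ("spatial", "primary", "relapse", "metastasis", "normal_reference")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


# ---------------------------------------------------------------------------
# Probe manifest


@dataclass(frozen=True)
class ProbeManifest:
    """Per-probe annotation: position, gene-region set, CGI relation, SNP flag.

    ``table`` is indexed by probe_id with columns ``chrom`` (str), ``pos``
    (int, 1-based), ``gene_regions`` (frozenset of GENE_REGION_CATEGORIES;
    empty means intergenic, reported as category ``IGR``), ``cgi_relation``
    (one of CGI_CATEGORIES) and ``is_snp_probe`` (bool). SNP probes report
    genotype, not methylation, and are excluded from all DMP analyses.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id in manifest: {dup!r}")
        if (t["pos"] < 1).any():
            bad = t.index[t["pos"] < 1][0]
            raise ValidationError(f"probe {bad!r} has position < 1")
        bad_cgi = set(t["cgi_relation"]) - set(CGI_CATEGORIES)
        if bad_cgi:
            raise ValidationError(f"unknown cgi_relation value(s): {sorted(bad_cgi)}")
        for pid, regions in t["gene_regions"].items():
            extra = set(regions) - set(GENE_REGION_CATEGORIES)
            if extra:
                raise ValidationError(
                    f"probe {pid!r} has unknown gene region(s): {sorted(extra)}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def snp_probe_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_snp_probe"]])

    @property
    def non_snp_probe_ids(self) -> list[str]:
        return list(self.table.index[~self.table["is_snp_probe"]])

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, int, Iterable[str], str, bool]],
    ) -> "ProbeManifest":
        """Build from (probe_id, chrom, pos, gene_regions, cgi_relation, is_snp)."""
        rows = list(records)
        table = pd.DataFrame(
            {
                "chrom": [r[1] for r in rows],
                "pos": [int(r[2]) for r in rows],
                "gene_regions": [frozenset(r[3]) for r in rows],
                "cgi_relation": [r[4] for r in rows],
                "is_snp_probe": [bool(r[5]) for r in rows],
            },
            index=pd.Index([r[0] for r in rows], name="probe_id"),
        )
        return cls(table)


def read_manifest(path: str | Path) -> ProbeManifest:
    """Read a probe manifest (TSV with columns probe_id, chrom, pos, strand,
    gene_regions, cgi_relation, is_snp).

    ``gene_regions`` is a semicolon list (duplicates removed, empty = IGR);
    ``strand`` is accepted and ignored; N/S shore/shelf orientation is folded.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    required = {"probe_id", "chrom", "pos", "gene_regions", "cgi_relation", "is_snp"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest {path} lacks column(s): {sorted(missing)}")

    def parse_regions(cell: str) -> frozenset[str]:
        return frozenset(x for x in cell.split(";") if x)

    def fold_cgi(cell: str) -> str:
        try:
            return _CGI_FOLD[cell]
        except KeyError:
            raise ValidationError(f"unknown cgi_relation {cell!r} in {path}") from None

    table = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].astype(int).to_numpy(),
            "gene_regions": [parse_regions(c) for c in df["gene_regions"]],
            "cgi_relation": [fold_cgi(c) for c in df["cgi_relation"]],
            "is_snp_probe": df["is_snp"].str.lower().isin(["1", "true", "yes"]).to_numpy(),
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    return ProbeManifest(table)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    t = manifest.table
    out = pd.DataFrame(
        {
            "probe_id": t.index,
            "chrom": t["chrom"].to_numpy(),
            "pos": t["pos"].to_numpy(),
            "strand": "*",
            "gene_regions": [";".join(sorted(r)) for r in t["gene_regions"]],
            "cgi_relation": t["cgi_relation"].to_numpy(),
            "is_snp": t["is_snp_probe"].astype(int).to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Beta matrix


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1], NaN = missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        for axis, name in ((v.index, "probe"), (v.columns, "sample")):
            if axis.has_duplicates:
                dup = axis[axis.duplicated()][0]
                raise ValidationError(f"duplicate {name} id: {dup!r}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing(self) -> pd.DataFrame:
        return self.values.isna()

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise ValidationError(f"unknown sample id {sample_id!r}")
        return self.values[sample_id]


def read_beta_matrix(path: str | Path, manifest: ProbeManifest | None = None) -> BetaMatrix:
    """Read a delimited beta matrix (first column probe_id, header = samples).

    Tab- or comma-delimited; empty cells or ``NA`` are missing. Values outside
    [0, 1] and duplicate ids are hard errors naming the offending cell.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sniff_sep(path), index_col=0,
        na_values=["NA"], keep_default_na=False,
    )
    df.index.name = "probe_id"
    bm = BetaMatrix(df.astype(float))
    if manifest is not None:
        unknown = bm.probe_ids.difference(manifest.probe_ids)
        if len(unknown):
            raise ValidationError(
                f"{len(unknown)} probe id(s) absent from the manifest, "
                f"e.g. {unknown[0]!r}"
            )
    return bm


def write_beta_matrix(beta: BetaMatrix, path: str | Path, sep: str = "\t") -> None:
    beta.values.to_csv(path, sep=sep, na_rep="NA")


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass
class SampleSheet:
    """Cohort design table: one row per sample.

    Columns: sample_id, patient_id, role (spatial | primary | relapse |
    metastasis | normal_reference), biopsy_index (int >= 1), purity
    (fraction, optional), relapse_interval (days, on relapse/metastasis rows,
    optional), group_label (free text, optional).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t["sample_id"][t["sample_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r} in sample sheet")
        bad = set(t["role"]) - set(SAMPLE_ROLES)
        if bad:
            raise ValidationError(f"unknown sample role(s): {sorted(bad)}")
        if (t["biopsy_index"] < 1).any():
            raise ValidationError("biopsy_index must be >= 1")
        pur = t["purity"].dropna()
        if ((pur < 0) | (pur > 1)).any():
            raise ValidationError("purity must lie in [0, 1]")
        ri = t["relapse_interval"].dropna()
        if (ri < 0).any():
            raise ValidationError("relapse_interval must be >= 0 days")
        for pid, grp in t.groupby("patient_id"):
            roles = grp["role"]
            if (roles.isin(["relapse", "metastasis"])).any():
                if (roles == "primary").sum() != 1:
                    raise ValidationError(
                        f"patient {pid!r} has relapse sample(s) but not exactly "
                        "one primary"
                    )
            if (roles == "spatial").any() and (roles == "spatial").sum() < 2:
                raise ValidationError(
                    f"spatial patient {pid!r} has fewer than 2 biopsies"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def patients(self, roles: Sequence[str] | None = None) -> list[str]:
        t = self.table
        if roles is not None:
            t = t[t["role"].isin(roles)]
        return sorted(t["patient_id"].unique())

    def samples_of(self, patient_id: str, roles: Sequence[str] | None = None) -> list[str]:
        t = self.table[self.table["patient_id"] == patient_id]
        if roles is not None:
            t = t[t["role"].isin(roles)]
        t = t.sort_values(["biopsy_index", "sample_id"])
        return list(t["sample_id"])

    def row(self, sample_id: str) -> pd.Series:
        t = self.table[self.table["sample_id"] == sample_id]
        if t.empty:
            raise ValidationError(f"unknown sample id {sample_id!r}")
        return t.iloc[0]

    def primary_relapse_pair(self, patient_id: str) -> tuple[str, str]:
        """The (primary, relapse-or-metastasis) pair of a temporal patient."""
        t = self.table[self.table["patient_id"] == patient_id]
        prim = t[t["role"] == "primary"]
        rel = t[t["role"].isin(["relapse", "metastasis"])]
        if len(prim) != 1 or len(rel) < 1:
            raise ValidationError(f"patient {patient_id!r} is not a primary/relapse pair")
        rel = rel.sort_values(["biopsy_index", "sample_id"])
        return prim["sample_id"].iloc[0], rel["sample_id"].iloc[0]

    def validate_against(self, beta: BetaMatrix) -> None:
        missing = set(self.sample_ids) - set(beta.sample_ids)
        if missing:
            raise ValidationError(
                f"sample sheet lists sample(s) absent from the beta matrix: "
                f"{sorted(missing)[:5]}"
            )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path)
    required = {"sample_id", "patient_id", "role", "biopsy_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet lacks column(s): {sorted(missing)}")
    for optional in ("purity", "relapse_interval", "group_label"):
        if optional not in df.columns:
            df[optional] = np.nan
    df["biopsy_index"] = df["biopsy_index"].astype(int)
    df["purity"] = pd.to_numeric(df["purity"], errors="coerce")
    df["relapse_interval"] = pd.to_numeric(df["relapse_interval"], errors="coerce")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Copy-number segments (IGV SEG)


@dataclass
class CnaSegmentSet:
    """Per-sample segmented log2 copy-number ratios.

    ``segments`` maps sample_id to a DataFrame with columns chrom, start, end
    (1-based inclusive) and seg_mean. Segments of one sample must not overlap
    within a chromosome.
    """

    segments: Mapping[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, df in self.segments.items():
            if (df["start"] > df["end"]).any():
                bad = df[df["start"] > df["end"]].iloc[0]
                raise ValidationError(
                    f"segment start > end for sample {sample!r} "
                    f"({bad['chrom']}:{bad['start']}-{bad['end']})"
                )
            for chrom, grp in df.groupby("chrom"):
                g = grp.sort_values("start")
                prev_end = None
                for _, row in g.iterrows():
                    if prev_end is not None and row["start"] <= prev_end:
                        raise ValidationError(
                            f"overlapping segments for sample {sample!r} on {chrom}"
                        )
                    prev_end = row["end"]

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.segments)

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "seg_mean"])
        return self.segments.get(sample_id, empty)


_SEG_ALIASES = {
    "id": "sample", "sample": "sample",
    "chrom": "chrom", "chromosome": "chrom",
    "loc.start": "start", "start": "start",
    "loc.end": "end", "end": "end",
    "seg.mean": "seg_mean", "seg_mean": "seg_mean",
}


def read_seg(path: str | Path) -> CnaSegmentSet:
    """Read an IGV SEG file (ID, chrom, loc.start, loc.end, [num.mark], seg.mean)."""
    df = pd.read_csv(path, sep="\t")
    cols = {}
    for c in df.columns:
        key = _SEG_ALIASES.get(c.strip().lower())
        if key:
            cols[key] = c
    needed = {"sample", "chrom", "start", "end", "seg_mean"}
    missing = needed - set(cols)
    if missing:
        raise ValidationError(f"SEG file {path} lacks column(s): {sorted(missing)}")
    segments: dict[str, pd.DataFrame] = {}
    for sample, grp in df.groupby(cols["sample"]):
        segments[str(sample)] = pd.DataFrame(
            {
                "chrom": grp[cols["chrom"]].astype(str).to_numpy(),
                "start": grp[cols["start"]].astype(int).to_numpy(),
                "end": grp[cols["end"]].astype(int).to_numpy(),
                "seg_mean": grp[cols["seg_mean"]].astype(float).to_numpy(),
            }
        ).reset_index(drop=True)
    return CnaSegmentSet(segments)


def write_seg(segset: CnaSegmentSet, path: str | Path) -> None:
    rows = []
    for sample in segset.sample_ids:
        df = segset.segments[sample]
        for _, r in df.iterrows():
            rows.append((sample, r["chrom"], int(r["start"]), int(r["end"]), r["seg_mean"]))
    out = pd.DataFrame(rows, columns=["ID", "chrom", "loc.start", "loc.end", "seg.mean"])
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Analysis configuration


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the analysis.

    dmp_delta_threshold: minimum |Δβ| (strict) for a differentially
        methylated position; 0.3 is the conventional 30% cut-off.
    cna_del_threshold: segment log2 ratio below which (strict) a region is
        treated as homozygously deleted and its probes removed.
    phylo_top_k / cluster_top_k / mds_top_k: numbers of most-variable probes
        used for per-patient trees, cohort clustering and cohort MDS.
    enrich_alpha: two-sided significance level for region enrichment.
    """

    dmp_delta_threshold: float = 0.3
    cna_del_threshold: float = -0.4
    phylo_top_k: int = 5000
    cluster_top_k: int = 10000
    mds_top_k: int = 20000
    enrich_alpha: float = 0.01
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dmp_delta_threshold < 1:
            raise ValidationError("dmp_delta_threshold must lie in (0, 1)")
        if not self.cna_del_threshold < 0:
            raise ValidationError("cna_del_threshold must be negative")
        for k in (self.phylo_top_k, self.cluster_top_k, self.mds_top_k):
            if k < 2:
                raise ValidationError("top_k values must be >= 2")
        if not 0 < self.enrich_alpha < 1:
            raise ValidationError("enrich_alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Newick + JSON reports


def write_newick(tree) -> str:
    """Serialize a tree (PhyloTree or rooted rendering) as Newick text.

    Branch lengths are included; leaf labels are the sample ids, quoted when
    they contain Newick metacharacters. Duplicate leaf labels are an error.
    """
    leaves = tree.leaves()
    if len(leaves) != len(set(leaves)):
        raise ValidationError("duplicate leaf labels in tree")
    return tree.to_newick()


def write_json_report(obj, path: str | Path) -> None:
    """Write a JSON report with a stable key order (schema: docs/methods.md)."""

    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json_report(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
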