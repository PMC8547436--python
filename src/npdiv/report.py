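"""Venn partitioning, ordered accumulation, geography and the pipeline.

These are the reporting analyses of the library-design workflow: which
fraction of chemistry is core to all groups versus private to one, how
much coverage each group adds when assembled abundant-first versus
rare-first, and whether any chemical cluster occupies a restricted
geographic range. :func:`run_pipeline` chains every stage and writes a
machine-readable summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, io, partition, preprocess, scaffolds, synth
from .containers import IncidenceMatrix
from .errors import DegenerateDataError

__all__ = [
    "VennPartition",
    "CoverageReport",
    "as_percent",
    "venn_partition",
    "ordered_accumulation",
    "geographic_summary",
    "run_pipeline",
    "validate_summary",
]


def as_percent(count: int, total: int) -> float:
    """Percentage at one decimal, rounded half away from zero.

    This is the convention that reproduces printed survey percentages
    from their (count, total) pairs, e.g. 539/1,661 -> 32.5.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= count <= total):
        raise ValueError("count must lie in [0, total]")
    pct = (Decimal(count) * 100) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class VennPartition:
    """Counts of items by the exact subset of groups containing them."""

    counts: dict  # frozenset of group labels -> count
    total: int
    groups: list

    def subset_count(self, *groups) -> int:
        return self.counts.get(frozenset(groups), 0)

    @property
    def core_count(self) -> int:
        """Items present in every group."""
        return self.counts.get(frozenset(self.groups), 0)

    def unique_count(self, group) -> int:
        """Items present only in the given group."""
        return self.counts.get(frozenset([group]), 0)

    def shared_count(self) -> int:
        """Items present in two or more groups."""
        return sum(c for s, c in self.counts.items() if len(s) >= 2)

    def as_table(self) -> pd.DataFrame:
        rows = [
            {
                "subset": "+".join(sorted(map(str, s))),
                "n_groups": len(s),
                "count": c,
                "percent": as_percent(c, self.total),
            }
            for s, c in sorted(
                self.counts.items(), key=lambda kv: (len(kv[0]), sorted(map(str, kv[0])))
            )
        ]
        return pd.DataFrame(rows)


def venn_partition(
    incidence: IncidenceMatrix, groups: pd.Series | None = None
) -> VennPartition:
    """Assign every item to the exact subset of groups in which it occurs.

    Group-level presence is the union over the group's isolates (one
    detection suffices). Items present in no group are excluded with a
    warning; needs at least two groups.
    """
    inc = incidence if groups is None else IncidenceMatrix(incidence.presence, groups)
    gp = inc.group_presence().astype(bool)
    group_labels = list(gp.columns)
    if len(group_labels) < 2:
        raise DegenerateDataError("Venn partition needs at least two groups")
    counts: dict[frozenset, int] = {}
    n_excluded = 0
    for _, row in gp.iterrows():
        subset = frozenset(gp.columns[row.to_numpy()])
        if not subset:
            n_excluded += 1
            continue
        counts[subset] = counts.get(subset, 0) + 1
    if n_excluded:
        warnings.warn(f"{n_excluded} items present in no group excluded", stacklevel=2)
    total = sum(counts.values())
    return VennPartition(counts=counts, total=total, groups=group_labels)


@dataclass
class CoverageReport:
    """Incremental coverage of groups added in a stated order."""

    order: list
    increments_raw: list  # exact fractions of the grand total, in [0, 1]
    increments_pct: list  # one-decimal percentages; last absorbs residue
    cumulative_pct: list
    item_kind: str = "feature"

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.order,
                "increment_raw": self.increments_raw,
                "increment_pct": self.increments_pct,
                "cumulative_pct": self.cumulative_pct,
            }
        )


def ordered_accumulation(
    incidence: IncidenceMatrix,
    order="largest-first",
    item_kind: str = "feature",
) -> CoverageReport:
    """Groupwise accumulation: how much new chemistry each group adds.

    ``order`` is a permutation of the group labels, or one of the
    built-ins "largest-first" / "smallest-first" by group size (ties
    broken by label). Each increment is the percentage of the grand
    total newly covered by the group; the final rounded increment
    absorbs the rounding residue so the cumulative percentage prints as
    exactly 100.0.
    """
    if incidence.groups is None:
        raise DegenerateDataError("ordered accumulation needs group labels")
    sizes = incidence.groups.value_counts()
    labels = set(sizes.index)
    if isinstance(order, str):
        if order == "largest-first":
            order = list(sizes.sort_values(ascending=False, kind="stable").index)
        elif order == "smallest-first":
            order = list(sizes.sort_values(ascending=True, kind="stable").index)
        else:
            raise ValueError(f"unknown built-in order {order!r}")
    else:
        order = list(order)
        if set(order) != labels or len(order) != len(labels):
            raise ValueError("order must be a permutation of the group labels")
    gp = incidence.group_presence().astype(bool)
    total = int((gp.any(axis=1)).sum())
    covered = np.zeros(len(gp), dtype=bool)
    increments_raw: list[float] = []
    for group in order:
        newly = gp[group].to_numpy() & ~covered
        covered |= gp[group].to_numpy()
        increments_raw.append(int(newly.sum()) / total)
    pct = [as_percent(round(frac * total), total) for frac in increments_raw]
    residue = round(100.0 - sum(pct), 1)
    pct[-1] = round(pct[-1] + residue, 1)
    cumulative = list(np.round(np.cumsum(pct), 1))
    return CoverageReport(
        order=order,
        increments_raw=increments_raw,
        increments_pct=pct,
        cumulative_pct=[float(c) for c in cumulative],
        item_kind=item_kind,
    )


def geographic_summary(
    metadata: pd.DataFrame,
    labels: pd.Series,
    restricted_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-group longitude/latitude bounding boxes and range flags.

    ``labels`` maps isolate_id to a group (e.g. chemical cluster).
    Groups whose longitudinal span is below ``restricted_fraction`` of
    the overall span are flagged as range-restricted. Isolates without
    coordinates are skipped with a warning.
    """
    meta = metadata.loc[~metadata["is_blank"]]
    coords = meta.groupby("isolate_id")[["lon", "lat"]].first()
    missing = coords.index[coords["lon"].isna() | coords["lat"].isna()]
    if len(missing):
        warnings.warn(f"{len(missing)} isolates lack coordinates; skipped", stacklevel=2)
        coords = coords.drop(missing)
    labels = pd.Series(labels)
    coords = coords.loc[coords.index.intersection(labels.index)]
    grouped = coords.groupby(labels.loc[coords.index])
    rows = []
    for group, sub in grouped:
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "lon_min": sub["lon"].min(),
                "lon_max": sub["lon"].max(),
                "lat_min": sub["lat"].min(),
                "lat_max": sub["lat"].max(),
                "lon_span": sub["lon"].max() - sub["lon"].min(),
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    overall = coords["lon"].max() - coords["lon"].min()
    out["range_restricted"] = (
        out["lon_span"] < restricted_fraction * overall if overall > 0 else False
    )
    return out


# --------------------------------------------------------------------------
# end-to-end pipeline
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of :func:`run_pipeline`.

    Either ``simulate`` holds a :class:`~npdiv.synth.GeneratorConfig`,
    or ``features``/``metadata``/``mgf`` point at input files.
    """

    simulate: synth.GeneratorConfig | None = None
    features: str | None = None
    metadata: str | None = None
    mgf: str | None = None
    outdir: str = "npdiv_out"
    blank_mode: str = "strict"
    fold: float = 3.0
    merge_mode: str = "mean"
    threshold: float = 0.0
    k_min: int = 2
    k_max: int = 10
    n_perm_permanova: int = 999
    coverage_fractions: tuple = (0.5, 0.75, 0.9, 0.95, 0.99)
    endpoint: int = 500
    min_cosine: float = 0.7
    min_matched: int = 6
    top_k: int = 10
    frag_tol: float = 0.02
    drop_singleton_scaffolds: bool = True
    seed: int = 0


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __init__(self, label):
            self.label = label

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {self.label!r} failed: {exc}") from exc
    return _Ctx(name)


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate? -> preprocess -> partition -> diversity -> network -> report.

    Writes all stage tables under ``config.outdir`` plus a single
    ``summary.json`` holding every headline number; returns the summary
    dict. Reruns with the same configuration and seed are byte-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": _jsonable_params(config)}

    with _stage("input"):
        if config.simulate is not None:
            table, metadata, spectra, truth = synth.generate_dataset(config.simulate)
            synth.write_dataset(outdir / "simulated", table, metadata, spectra, truth)
        else:
            if not (config.features and config.metadata):
                raise ValueError("either simulate or features+metadata must be given")
            table = io.read_feature_table(config.features)
            metadata = io.read_metadata(config.metadata)
            spectra = io.read_mgf(config.mgf) if config.mgf else []
        summary["input"] = {
            "n_features_raw": int(table.n_features),
            "n_samples": int(table.n_samples),
        }

    with _stage("preprocess"):
        normalized, incidence = preprocess.preprocess_pipeline(
            table,
            metadata,
            blank_mode=config.blank_mode,
            fold=config.fold,
            merge_mode=config.merge_mode,
            threshold=config.threshold,
        )
        io.write_feature_table(normalized, outdir / "normalized.csv")
        io.write_incidence(incidence, outdir / "incidence_features.csv")
        summary["preprocess"] = {
            "n_features": int(incidence.S_obs),
            "n_isolates": int(incidence.T),
            "singleton_fraction": incidence.Q1 / incidence.S_obs,
        }

    with _stage("partition"):
        dm = partition.distance_matrix(normalized)
        dm.to_frame().to_csv(outdir / "distances.csv")
        ordination = partition.pcoa(dm)
        ordination.coordinates.to_csv(outdir / "pcoa_coordinates.csv")
        clustering = partition.cluster_isolates(
            dm, k_range=range(config.k_min, config.k_max + 1)
        )
        clustering.labels.rename("cluster").to_csv(outdir / "clusters.tsv", sep="\t")
        clades = incidence.groups
        perm_clade = partition.permanova(
            dm, clades.loc[dm.ids], n_perm=config.n_perm_permanova, seed=config.seed
        )
        perm_cluster = partition.permanova(
            dm,
            clustering.labels.loc[dm.ids],
            n_perm=config.n_perm_permanova,
            seed=config.seed,
        )
        summary["partition"] = {
            "selected_k": clustering.k,
            "silhouette_by_k": {str(k): v for k, v in sorted(clustering.silhouette_by_k.items())},
            "permanova_clade": {"pseudo_F": perm_clade.pseudo_F, "p_value": perm_clade.p_value},
            "permanova_cluster": {
                "pseudo_F": perm_cluster.pseudo_F,
                "p_value": perm_cluster.p_value,
            },
        }

    with _stage("diversity"):
        richness = diversity.alpha_richness(incidence)
        summary_rich = diversity.compare_richness(richness, incidence.groups)
        summary_rich.group_stats.to_csv(outdir / "richness_by_clade.tsv", sep="\t")
        curve = diversity.rarefaction_curve(incidence, endpoint=config.endpoint)
        curve.data.to_csv(outdir / "curve_all.csv", index=False)
        targets = diversity.coverage_targets(incidence, config.coverage_fractions)
        pd.DataFrame(
            {"fraction": list(targets), "n_isolates": list(targets.values())}
        ).to_csv(outdir / "coverage_targets.csv", index=False)
        slopes = {}
        for clade in sorted(incidence.groups.unique()):
            sub = incidence.for_group(clade)
            slopes[str(clade)] = diversity.end_slope(sub)
        summary["diversity"] = {
            "richness_median_by_group": {
                str(g): float(v) for g, v in summary_rich.group_stats["median"].items()
            },
            "anova_F": summary_rich.anova_F,
            "anova_p": summary_rich.anova_p,
            "coverage_targets": {str(p): int(t) for p, t in targets.items()},
            "end_slope_by_group": slopes,
        }

    with _stage("network"):
        summary["scaffolds"] = {}
        scaffold_inc = None
        if spectra:
            network = scaffolds.build_network(
                spectra,
                min_cosine=config.min_cosine,
                min_matched=config.min_matched,
                top_k=config.top_k,
                frag_tol=config.frag_tol,
            )
            network.edge_table().to_csv(outdir / "edges.tsv", sep="\t", index=False)
            assignment = scaffolds.assignment_from_network(network)
            assignment.to_csv(outdir / "scaffold_map.tsv", sep="\t")
            scaffold_inc, n_dropped = scaffolds.scaffold_incidence(
                assignment, incidence, drop_singletons=config.drop_singleton_scaffolds
            )
            io.write_incidence(scaffold_inc, outdir / "incidence_scaffolds.csv")
            summary["scaffolds"] = {
                "n_scaffolds": int(network.n_scaffolds),
                "n_singletons_removed": int(n_dropped),
                "n_nonsingleton": int(scaffold_inc.presence.shape[0]),
            }

    with _stage("report"):
        venn_features = venn_partition(incidence)
        venn_features.as_table().to_csv(outdir / "venn_features.csv", index=False)
        summary["venn_features"] = _venn_summary(venn_features)
        if scaffold_inc is not None:
            venn_scaffolds = venn_partition(scaffold_inc)
            venn_scaffolds.as_table().to_csv(outdir / "venn_scaffolds.csv", index=False)
            summary["venn_scaffolds"] = _venn_summary(venn_scaffolds)
            acc_inc = scaffold_inc
        else:
            acc_inc = incidence
        acc_large = ordered_accumulation(acc_inc, "largest-first")
        acc_small = ordered_accumulation(acc_inc, "smallest-first")
        acc_large.as_table().to_csv(outdir / "accumulation_largest_first.csv", index=False)
        acc_small.as_table().to_csv(outdir / "accumulation_smallest_first.csv", index=False)
        summary["ordered_accumulation"] = {
            "largest_first": {
                "order": [str(g) for g in acc_large.order],
                "increments_pct": acc_large.increments_pct,
            },
            "smallest_first": {
                "order": [str(g) for g in acc_small.order],
                "increments_pct": acc_small.increments_pct,
            },
        }
        geo = geographic_summary(metadata, _cluster_by_isolate(clustering.labels))
        geo.to_csv(outdir / "geography.csv")
        summary["geography"] = {
            str(g): {
                "n": int(row["n"]),
                "lon_span": float(row["lon_span"]),
                "range_restricted": bool(row["range_restricted"]),
            }
            for g, row in geo.iterrows()
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _cluster_by_isolate(labels: pd.Series) -> pd.Series:
    """Cluster labels are already per isolate after replicate merging."""
    return labels


def _venn_summary(venn: VennPartition) -> dict:
    return {
        "total": venn.total,
        "core_count": venn.core_count,
        "core_percent": as_percent(venn.core_count, venn.total),
        "unique_counts": {
            str(g): venn.unique_count(g) for g in venn.groups
        },
        "shared_two_plus": venn.shared_count(),
    }


def _jsonable_params(config: PipelineConfig) -> dict:
    out = {}
    for key, value in vars(config).items():
        if isinstance(value, synth.GeneratorConfig):
            sub = {}
            for k, v in vars(value).items():
                if isinstance(v, tuple):
                    v = list(v)
                elif isinstance(v, dict):
                    v = {str(kk): list(vv) for kk, vv in v.items()}
                sub[k] = v
            out[key] = sub
        elif isinstance(value, tuple):
            out[key] = list(value)
        else:
            out[key] = value
    return out


def validate_summary(summary: dict, schema: dict | None = None) -> None:
    """Check a pipeline summary against the bundled structural schema.

    The schema is a nested mapping of required keys to type names
    ("object", "number", "integer", "string", "boolean", "any");
    raises ``ValueError`` on the first violation.
    """
    if schema is None:
        schema = json.loads(
            resources.files("npdiv").joinpath("summary_schema.json").read_text()
        )
    _validate_node(summary, schema["required"], path="summary")


_TYPE_CHECKS = {
    "object": lambda v: isinstance(v, dict),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "string": lambda v: isinstance(v, str),
    "boolean": lambda v: isinstance(v, bool),
    "any": lambda v: True,
}


def _validate_node(value: dict, required: dict, path: str) -> None:
    for key, spec in required.items():
        if key not in value:
            raise ValueError(f"{path}: missing required key {key!r}")
        child = value[key]
        if isinstance(spec, dict):
            if not isinstance(child, dict):
                raise ValueError(f"{path}.{key}: expected object")
            _validate_node(child, spec, f"{path}.{key}")
        else:
            if not _TYPE_CHECKS[spec](child):
                raise ValueError(f"{path}.{key}: expected {spec}")
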