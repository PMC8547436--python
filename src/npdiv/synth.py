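"""Synthetic metabolomics datasets with known chemical structure.

The generator emulates the statistical shape of a culture-collection
metabolomics survey: a set of fungal isolates partitioned into uneven
barcode clades, each clade carrying a chemotype (a chemical cluster)
whose feature pool combines a small genus-wide core, a large
chemotype-specific pool, and features shared pairwise between clades.
Two wrinkles mirror what such surveys find in practice: one clade hides
two distinct chemotypes, and a few isolates of other clades express the
chemotype of a "donor" cluster (chemically embedded isolates). A
configurable fraction of features is present in exactly one isolate,
duplicate cultures are produced per isolate, blank injections carry
their own artifact features, and every non-blank feature belongs to a
scaffold whose members share alignable MS/MS peaks under shift-aware
matching.

Everything is driven by one integer seed; a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureTable
from .errors import InfeasibleConfigError
from .io import write_feature_table, write_metadata, write_mgf
from .scaffolds import Spectrum

__all__ = ["GeneratorConfig", "GroundTruth", "generate_dataset", "generate_spectra", "write_dataset"]

# Continental-US style longitude/latitude boxes per chemical cluster.
# Clusters 1, 2 and 6 range widely; cluster 3 avoids the southeast,
# cluster 4 is moderately restricted and cluster 5 occurs only in the far
# west, giving the report stage a range-restricted group to flag.
_DEFAULT_GEO_BOXES = {
    1: (-124.0, -68.0, 26.0, 48.0),
    2: (-124.0, -68.0, 26.0, 48.0),
    3: (-124.0, -90.0, 30.0, 48.0),
    4: (-124.0, -95.0, 28.0, 45.0),
    5: (-124.0, -114.0, 33.0, 48.0),
    6: (-124.0, -68.0, 26.0, 48.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic survey.

    The defaults describe a stylized 198-isolate collection in five
    clades (the largest holding 111 isolates), with clade pool sizes
    ordered so that per-isolate richness ranks U > Y > V > W > X, an 18%
    singleton-feature fraction, duplicate cultures, and a hidden
    chemotype split inside the second clade giving six true chemical
    clusters in total.
    """

    n_clades: int = 5
    clade_sizes: tuple[int, ...] = (111, 30, 25, 18, 14)
    clade_names: tuple[str, ...] = ("U", "V", "W", "X", "Y")
    n_core_features: int = 60
    n_clade_features: tuple[int, ...] = (300, 200, 80, 60, 140)
    n_pairwise_shared_features: int = 100
    singleton_fraction: float = 0.18
    # rare tail beyond singletons: fraction of final features present in
    # exactly two isolates of one clade, so Q2 > 0 and the Chao2
    # asymptote stays finite, as in real surveys
    doubleton_fraction: float = 0.03
    p_detect_core: float = 0.95
    p_detect_clade: float = 0.9
    # clade V hides two chemotypes; its pool is split between them, with
    # split_pool_overlap controlling how chemically distinct they are
    hidden_split_clade: int = 1
    split_pool_overlap: float = 0.0
    # a few isolates of clades U, V and X express the chemotype of the
    # donor clade's cluster (chemical cluster 2, carried by clade W)
    embedded_donor_clade: int = 2
    embedded_host_clades: tuple[int, ...] = (0, 1, 3)
    embedded_cluster_rate: float = 0.03
    n_replicates_per_isolate: int = 2
    n_blanks: int = 4
    n_blank_features: int = 30
    blank_contamination_rate: float = 0.3
    abundance_lognormal_mu: float = 10.0
    abundance_lognormal_sigma: float = 1.0
    n_scaffolds: int = 600
    # most molecular-network components in culture-collection surveys
    # are single features; the rest average a handful of members
    scaffold_singleton_fraction: float = 0.7
    scaffold_concentration: float = 1.0
    peaks_per_scaffold_range: tuple[int, int] = (10, 16)
    shiftable_peak_fraction: float = 0.3
    fragment_noise_peaks: int = 2
    min_matched_peaks: int = 6
    cluster_geo_boxes: dict = field(default_factory=lambda: dict(_DEFAULT_GEO_BOXES))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.clade_sizes) != self.n_clades or len(self.clade_names) != self.n_clades:
            raise InfeasibleConfigError("clade_sizes/clade_names length must equal n_clades")
        if len(self.n_clade_features) != self.n_clades:
            raise InfeasibleConfigError("n_clade_features length must equal n_clades")
        if any(s < 1 for s in self.clade_sizes):
            raise InfeasibleConfigError("every clade needs at least one isolate")
        if not (0 <= self.singleton_fraction < 1):
            raise InfeasibleConfigError("singleton_fraction must be in [0, 1)")
        if self.doubleton_fraction < 0 or (
            self.singleton_fraction + self.doubleton_fraction
        ) >= 1:
            raise InfeasibleConfigError(
                "singleton_fraction + doubleton_fraction must be below 1"
            )
        for p in (self.p_detect_core, self.p_detect_clade):
            if not (0 < p <= 1):
                raise InfeasibleConfigError("detection probabilities must be in (0, 1]")
        if self.peaks_per_scaffold_range[0] < self.min_matched_peaks:
            raise InfeasibleConfigError(
                "peaks_per_scaffold_range minimum below min_matched_peaks"
            )
        if self.hidden_split_clade is not None and not (
            0 <= self.hidden_split_clade < self.n_clades
        ):
            raise InfeasibleConfigError("hidden_split_clade out of range")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("clade_sizes", "clade_names", "n_clade_features",
                    "peaks_per_scaffold_range", "embedded_host_clades"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "cluster_geo_boxes" in raw:
            raw["cluster_geo_boxes"] = {
                int(k): tuple(v) for k, v in raw["cluster_geo_boxes"].items()
            }
        return cls(**raw)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Bookkeeping of what the generator actually did.

    ``features`` is indexed by feature_id with columns ``category`` (one
    of core, clade_specific(<clade>), pairwise_shared(<g>,<h>),
    singleton, blank_artifact), ``scaffold_id`` (empty for blank
    artifacts) and ``clusters`` (the set of chemical clusters whose
    isolates are eligible to express the feature, as a sorted
    comma-joined string; empty for blank artifacts). ``isolates`` is
    indexed by isolate_id with columns ``clade`` and ``true_cluster``.
    """

    features: pd.DataFrame
    isolates: pd.DataFrame

    @property
    def true_n_clusters(self) -> int:
        return int(self.isolates["true_cluster"].nunique())

    @property
    def blank_artifact_ids(self) -> pd.Index:
        return self.features.index[self.features["category"] == "blank_artifact"]

    @property
    def nonblank_ids(self) -> pd.Index:
        return self.features.index[self.features["category"] != "blank_artifact"]

    def scaffold_partition(self) -> pd.Series:
        """True scaffold label per non-blank feature."""
        return self.features.loc[self.nonblank_ids, "scaffold_id"]


def _chemotype_map(config: GeneratorConfig) -> dict[int, tuple[int, ...]]:
    """Clade index -> tuple of chemical cluster labels carried by the clade.

    Clusters are numbered 1..K with the split clade contributing two
    labels, mirroring a survey where five clades harbor six clusters.
    """
    mapping: dict[int, tuple[int, ...]] = {}
    next_label = 1
    for clade in range(config.n_clades):
        if clade == config.hidden_split_clade:
            mapping[clade] = (0, 0)  # placeholder, filled after the loop
        else:
            mapping[clade] = (next_label,)
            next_label += 1
    if config.hidden_split_clade is not None:
        mapping[config.hidden_split_clade] = (next_label, next_label + 1)
    return mapping


def generate_dataset(config: GeneratorConfig):
    """Simulate one survey.

    Returns
    -------
    (FeatureTable, metadata DataFrame, list[Spectrum], GroundTruth)
        The feature table has one column per replicate culture and per
        blank, in the MZmine export dialect when written to disk.
    """
    rng = np.random.default_rng(config.seed)
    chemo_map = _chemotype_map(config)

    # ---- isolates: clade membership and chemotype -----------------------
    isolate_ids = [f"ISO{i + 1:03d}" for i in range(sum(config.clade_sizes))]
    clade_of = np.repeat(np.arange(config.n_clades), config.clade_sizes)
    cluster_of = np.empty(len(isolate_ids), dtype=int)
    for clade in range(config.n_clades):
        idx = np.nonzero(clade_of == clade)[0]
        labels = chemo_map[clade]
        if len(labels) == 2:
            # hidden split: first half one chemotype, second half the other
            half = len(idx) // 2
            cluster_of[idx[:half]] = labels[0]
            cluster_of[idx[half:]] = labels[1]
        else:
            cluster_of[idx] = labels[0]
    # embedded isolates: a few members of the host clades adopt the donor
    # cluster's chemotype wholesale
    donor_cluster = chemo_map[config.embedded_donor_clade][0]
    if config.embedded_cluster_rate > 0:
        hosts = np.nonzero(np.isin(clade_of, config.embedded_host_clades))[0]
        n_embedded = int(round(config.embedded_cluster_rate * hosts.size))
        if n_embedded:
            chosen = rng.choice(hosts, size=n_embedded, replace=False)
            cluster_of[chosen] = donor_cluster

    n_isolates = len(isolate_ids)
    all_clusters = sorted({c for labels in chemo_map.values() for c in labels})

    # ---- base feature pools and eligibility -----------------------------
    categories: list[str] = []
    eligible: list[np.ndarray] = []  # boolean masks over isolates
    detect_p: list[float] = []
    clusters_of_feature: list[tuple[int, ...]] = []

    def add_features(n, category, mask, p, clusters):
        for _ in range(n):
            categories.append(category)
            eligible.append(mask)
            detect_p.append(p)
            clusters_of_feature.append(clusters)

    add_features(
        config.n_core_features,
        "core",
        np.ones(n_isolates, dtype=bool),
        config.p_detect_core,
        tuple(all_clusters),
    )
    for clade in range(config.n_clades):
        name = config.clade_names[clade]
        labels = chemo_map[clade]
        pool = config.n_clade_features[clade]
        if len(labels) == 2:
            # split the pool between the two hidden chemotypes, with an
            # optional shared slice controlling how distinct they are
            n_shared = int(round(config.split_pool_overlap * pool))
            n_each = (pool - n_shared) // 2
            for lab in labels:
                mask = cluster_of == lab
                add_features(n_each, f"clade_specific({name})", mask,
                             config.p_detect_clade, (lab,))
            if n_shared:
                mask = np.isin(cluster_of, labels)
                add_features(n_shared, f"clade_specific({name})", mask,
                             config.p_detect_clade, tuple(labels))
        else:
            mask = cluster_of == labels[0]
            add_features(pool, f"clade_specific({name})", mask,
                         config.p_detect_clade, (labels[0],))
    # pairwise-shared features: random unordered clade pairs
    pairs = [(g, h) for g in range(config.n_clades) for h in range(g + 1, config.n_clades)]
    for _ in range(config.n_pairwise_shared_features):
        g, h = pairs[rng.integers(len(pairs))]
        labels = tuple(sorted(set(chemo_map[g]) | set(chemo_map[h])))
        mask = np.isin(cluster_of, labels)
        add_features(
            1,
            f"pairwise_shared({config.clade_names[g]},{config.clade_names[h]})",
            mask,
            config.p_detect_clade,
            labels,
        )

    # ---- Bernoulli detection -> isolate-level incidence -----------------
    n_base = len(categories)
    incidence = np.zeros((n_base, n_isolates), dtype=bool)
    for i in range(n_base):
        mask = eligible[i]
        draws = rng.random(n_isolates) < detect_p[i]
        incidence[i] = mask & draws
    detected = incidence.sum(axis=1) > 0
    n_dropped = int((~detected).sum())
    incidence = incidence[detected]
    categories = [c for c, d in zip(categories, detected) if d]
    clusters_of_feature = [c for c, d in zip(clusters_of_feature, detected) if d]

    # ---- rare-tail injection (singletons and doubletons) ----------------
    # Features present in exactly one isolate are injected until their
    # realized fraction matches singleton_fraction to within one feature;
    # a smaller doubleton tail (two isolates of one clade, i.e. clade-pool
    # features at very low detection) keeps Q2 positive.
    n0 = incidence.shape[0]
    n_acc_single = int((incidence.sum(axis=1) == 1).sum())
    n_acc_double = int((incidence.sum(axis=1) == 2).sum())
    f, g = config.singleton_fraction, config.doubleton_fraction
    n_inject = n_double = 0
    if f > 0 or g > 0:
        if n_acc_single - f * n0 > 1:
            raise InfeasibleConfigError(
                "detection noise already produces more singletons than the "
                "configured singleton_fraction allows"
            )
        n_final = (n0 - n_acc_single - n_acc_double) / (1 - f - g)
        n_inject = max(0, math.ceil(f * n_final - n_acc_single)) if f > 0 else 0
        n_double = max(0, round(g * n_final - n_acc_double)) if g > 0 else 0
    if n_inject:
        hosts = rng.integers(n_isolates, size=n_inject)
        singleton_rows = np.zeros((n_inject, n_isolates), dtype=bool)
        singleton_rows[np.arange(n_inject), hosts] = True
        incidence = np.vstack([incidence, singleton_rows])
        categories.extend(["singleton"] * n_inject)
        clusters_of_feature.extend(
            [(int(cluster_of[h]),) for h in hosts]
        )
    if n_double:
        double_rows = np.zeros((n_double, n_isolates), dtype=bool)
        eligible_clades = [
            c for c in range(config.n_clades) if (clade_of == c).sum() >= 2
        ]
        for i in range(n_double):
            clade = eligible_clades[rng.integers(len(eligible_clades))]
            members = np.nonzero(clade_of == clade)[0]
            pair = rng.choice(members, size=2, replace=False)
            double_rows[i, pair] = True
            categories.append(f"clade_specific({config.clade_names[clade]})")
            clusters_of_feature.append(
                tuple(sorted({int(cluster_of[p]) for p in pair}))
            )
        incidence = np.vstack([incidence, double_rows])

    n_nonblank = incidence.shape[0]
    feature_ids = [f"F{i + 1:05d}" for i in range(n_nonblank)]

    # ---- scaffold assignment (non-blank features only) ------------------
    scaffold_ids = _assign_scaffolds(rng, n_nonblank, config)

    # ---- spectra ---------------------------------------------------------
    truth_features = pd.DataFrame(
        {
            "category": categories,
            "scaffold_id": scaffold_ids,
            "clusters": [",".join(map(str, c)) for c in clusters_of_feature],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    spectra = generate_spectra(truth_features, config, rng=rng)
    precursors = {s.feature_id: s.precursor_mz for s in spectra}

    # ---- blank artifact features ----------------------------------------
    blank_ids = [f"B{i + 1:04d}" for i in range(config.n_blank_features)]

    # ---- samples: replicate cultures and blanks -------------------------
    culture_cols, culture_iso = [], []
    for iso_idx, iso in enumerate(isolate_ids):
        for rep in range(1, config.n_replicates_per_isolate + 1):
            culture_cols.append(f"{iso}_r{rep}")
            culture_iso.append(iso_idx)
    blank_cols = [f"BLANK_{j + 1}" for j in range(config.n_blanks)]
    culture_iso = np.array(culture_iso)

    n_features_total = n_nonblank + config.n_blank_features
    n_samples = len(culture_cols) + len(blank_cols)
    areas = np.zeros((n_features_total, n_samples))

    # abundances: a feature present in an isolate appears in every one of
    # its replicate cultures, with independent log-normal peak areas
    present_cultures = incidence[:, culture_iso]  # (n_nonblank, n_cultures)
    n_pos = int(present_cultures.sum())
    draws = rng.lognormal(
        config.abundance_lognormal_mu, config.abundance_lognormal_sigma, size=n_pos
    )
    areas[:n_nonblank, : len(culture_cols)][present_cultures] = draws

    # blank artifacts: in every blank, plus a random subset of cultures
    if config.n_blank_features:
        contaminated = rng.random((config.n_blank_features, len(culture_cols))) \
            < config.blank_contamination_rate
        n_pos = int(contaminated.sum())
        areas[n_nonblank:, : len(culture_cols)][contaminated] = rng.lognormal(
            config.abundance_lognormal_mu - 2,
            config.abundance_lognormal_sigma,
            size=n_pos,
        )
        areas[n_nonblank:, len(culture_cols):] = rng.lognormal(
            config.abundance_lognormal_mu - 2,
            config.abundance_lognormal_sigma,
            size=(config.n_blank_features, len(blank_cols)),
        )

    # ---- feature m/z and retention time ---------------------------------
    all_ids = feature_ids + blank_ids
    mz = np.empty(n_features_total)
    mz[:n_nonblank] = [precursors[fid] for fid in feature_ids]
    mz[n_nonblank:] = np.round(rng.uniform(150.0, 900.0, config.n_blank_features), 4)
    rt = np.round(rng.uniform(0.5, 10.5, n_features_total), 3)

    table = FeatureTable(
        pd.DataFrame(
            areas,
            index=pd.Index(all_ids, name="feature_id"),
            columns=culture_cols + blank_cols,
        ),
        pd.Series(mz, index=pd.Index(all_ids, name="feature_id"), name="mz"),
        pd.Series(rt, index=pd.Index(all_ids, name="feature_id"), name="rt"),
    )

    # ---- metadata --------------------------------------------------------
    lon = np.empty(n_isolates)
    lat = np.empty(n_isolates)
    for i in range(n_isolates):
        box = config.cluster_geo_boxes.get(int(cluster_of[i]))
        if box is None:
            box = (-124.0, -68.0, 26.0, 48.0)
        lon[i] = rng.uniform(box[0], box[1])
        lat[i] = rng.uniform(box[2], box[3])
    rows = []
    for col, iso_idx in zip(culture_cols, culture_iso):
        rep = int(col.rsplit("_r", 1)[1])
        rows.append(
            {
                "sample_id": col,
                "isolate_id": isolate_ids[iso_idx],
                "clade": config.clade_names[clade_of[iso_idx]],
                "replicate": rep,
                "is_blank": False,
                "lon": round(lon[iso_idx], 5),
                "lat": round(lat[iso_idx], 5),
            }
        )
    for col in blank_cols:
        rows.append(
            {
                "sample_id": col,
                "isolate_id": "",
                "clade": "",
                "replicate": 0,
                "is_blank": True,
                "lon": np.nan,
                "lat": np.nan,
            }
        )
    metadata = pd.DataFrame(rows).set_index("sample_id", drop=False)

    # ---- ground truth -----------------------------------------------------
    blank_truth = pd.DataFrame(
        {
            "category": "blank_artifact",
            "scaffold_id": "",
            "clusters": "",
        },
        index=pd.Index(blank_ids, name="feature_id"),
    )
    truth = GroundTruth(
        features=pd.concat([truth_features, blank_truth]),
        isolates=pd.DataFrame(
            {
                "isolate_id": isolate_ids,
                "clade": [config.clade_names[c] for c in clade_of],
                "true_cluster": cluster_of,
            }
        ).set_index("isolate_id", drop=False),
    )
    truth.features.attrs["n_dropped_undetected"] = n_dropped
    return table, metadata, spectra, truth


def _assign_scaffolds(rng: np.random.Generator, n_features: int, config: GeneratorConfig):
    """Skewed feature -> scaffold assignment.

    A configurable majority of scaffolds hold exactly one feature; the
    remaining features are spread over the multi-member scaffolds by a
    Dirichlet-multinomial on top of a guaranteed two members each,
    reproducing the long singleton tail plus a modest number of larger
    families seen in real molecular networks.
    """
    n_single = int(round(config.scaffold_singleton_fraction * config.n_scaffolds))
    n_multi = config.n_scaffolds - n_single
    minimum = n_single + 2 * n_multi
    if n_features < minimum:
        raise InfeasibleConfigError(
            f"{n_features} features cannot fill {config.n_scaffolds} scaffolds "
            f"({n_single} singletons + {n_multi} multi-member)"
        )
    sizes = np.ones(config.n_scaffolds, dtype=int)
    if n_multi:
        sizes[n_single:] = 2
        extra = n_features - minimum
        if extra:
            weights = rng.dirichlet(np.full(n_multi, config.scaffold_concentration))
            sizes[n_single:] += rng.multinomial(extra, weights)
    labels = np.repeat(np.arange(config.n_scaffolds), sizes)
    rng.shuffle(labels)
    return [f"TS{a + 1:04d}" for a in labels]


def generate_spectra(truth_features: pd.DataFrame, config: GeneratorConfig, rng=None):
    """MS/MS spectra for every non-blank feature, structured by scaffold.

    Each scaffold has a template: a random fragment peak list, a base
    precursor mass, and a fixed subset of "shiftable" peaks (the part of
    the molecule that varies between members). A member spectrum applies
    its own precursor offset to the shiftable peaks, jitters
    intensities, and adds low-intensity noise peaks — so any two members
    share all template peaks under shift-aware matching while spectra
    from different scaffolds share essentially none.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    nonblank = truth_features.index[truth_features["category"] != "blank_artifact"]
    lo, hi = config.peaks_per_scaffold_range
    templates: dict[str, dict] = {}
    spectra: list[Spectrum] = []
    for fid in nonblank:
        sid = truth_features.at[fid, "scaffold_id"]
        if sid not in templates:
            n_peaks = int(rng.integers(lo, hi + 1))
            precursor = float(rng.uniform(250.0, 900.0))
            frag_mz = np.sort(rng.uniform(50.0, precursor - 20.0, n_peaks))
            intensity = rng.uniform(0.2, 1.0, n_peaks)
            shiftable = rng.random(n_peaks) < config.shiftable_peak_fraction
            templates[sid] = {
                "precursor": precursor,
                "mz": frag_mz,
                "intensity": intensity,
                "shiftable": shiftable,
            }
        tpl = templates[sid]
        delta = float(rng.uniform(0.0, 80.0))
        member_mz = tpl["mz"] + np.where(tpl["shiftable"], delta, 0.0)
        member_int = tpl["intensity"] * np.exp(rng.normal(0.0, 0.1, tpl["mz"].size))
        if config.fragment_noise_peaks:
            noise_mz = rng.uniform(50.0, tpl["precursor"] + delta, config.fragment_noise_peaks)
            noise_int = np.full(config.fragment_noise_peaks, 0.03 * member_int.max())
            member_mz = np.concatenate([member_mz, noise_mz])
            member_int = np.concatenate([member_int, noise_int])
        spectra.append(
            Spectrum(
                feature_id=str(fid),
                precursor_mz=round(tpl["precursor"] + delta, 4),
                mz=np.round(member_mz, 4),
                intensity=np.round(member_int, 6),
            )
        )
    return spectra


def write_dataset(outdir, table, metadata, spectra, truth: GroundTruth) -> dict:
    """Write the generated dataset as plain-text files.

    Produces features.csv (MZmine dialect), metadata.tsv, spectra.mgf,
    truth_features.tsv and truth_isolates.tsv; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "features.csv",
        "metadata": outdir / "metadata.tsv",
        "spectra": outdir / "spectra.mgf",
        "truth_features": outdir / "truth_features.tsv",
        "truth_isolates": outdir / "truth_isolates.tsv",
    }
    write_feature_table(table, paths["features"])
    write_metadata(metadata, paths["metadata"])
    write_mgf(spectra, paths["spectra"])
    truth.features.to_csv(paths["truth_features"], sep="\t")
    truth.isolates.to_csv(paths["truth_isolates"], sep="\t", index=False)
    return paths
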