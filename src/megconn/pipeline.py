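"""Study orchestration: simulate -> beamform -> connect -> stats.

Each stage is a function over files in a study directory, so the CLI
subcommands and `run_study` compose identically and a run is reproducible
bit-for-bit from its seed and resolved configuration (whose SHA-256 hash
is recorded alongside every output).

Statistical hierarchy: per band, the whole-brain PLI group test gates the
post-hoc analyses — per-ROI permutation tests and within-RSN group tests
run only for bands with a significant whole-brain difference, and
covariate correlations only for networks with a significant group
difference in that band.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .bands import CANONICAL_BANDS, get_band
from .beamformer import compute_covariance, compute_weights, \
    reconstruct_voxels, roi_band_series
from .cohort import (CovariateLink, EffectSpec, RSNEffect, covariates_frame,
                     default_effect_spec, iter_cohort)
from .connectivity import adjacency, node_strength, rsn_mean_pli, \
    whole_brain_mean
from .geometry import generate_geometry
from .io import (append_recording_h5, read_covariates_tsv,
                 read_recordings_h5, read_rsns_json, write_adjacency_csv,
                 write_atlas_json, write_beamformer_h5,
                 write_covariates_tsv, write_results_tsv, write_rsns_json,
                 write_sensors_csv)
from .rsn import DEFAULT_RSNS
from .stats import (discard_outliers, effect_modification_regression,
                    ks_normality, mann_whitney, permutation_roi_test,
                    spearman)


class GeometryConfig(BaseModel):
    n_channels: int = 151
    n_rois: int = 78
    voxels_per_roi: int = 5
    head_radius: float = 0.09
    sensor_radius: float = 0.12
    roi_shell_radius: float = 0.07
    cluster_radius: float = 0.004


class RSNEffectConfig(BaseModel):
    band: str
    rsn: str
    control_kappa: float = Field(gt=0)
    patient_kappa: float = Field(gt=0)


class CovariateLinkConfig(BaseModel):
    covariate: str
    band: str
    rsn: str
    rho: float = Field(gt=-1.0, lt=1.0)
    group: str = "both"


class EffectConfig(BaseModel):
    baseline_kappa: float = Field(default=2.0, gt=0)
    kappa_sigma: float = Field(default=0.35, ge=0)
    lag_delta: float = Field(default=float(np.pi / 2))
    amplitude_snr: float = Field(default=2.0, gt=0)
    effects: list[RSNEffectConfig] | None = None
    links: list[CovariateLinkConfig] | None = None

    def to_spec(self) -> EffectSpec:
        default = default_effect_spec()
        effects = (default.effects if self.effects is None else
                   [RSNEffect(e.band, e.rsn, e.control_kappa,
                              e.patient_kappa) for e in self.effects])
        links = (default.links if self.links is None else
                 [CovariateLink(ln.covariate, ln.band, ln.rsn, ln.rho,
                                ln.group) for ln in self.links])
        return EffectSpec(baseline_kappa=self.baseline_kappa,
                          kappa_sigma=self.kappa_sigma,
                          lag_delta=self.lag_delta,
                          amplitude_snr=self.amplitude_snr,
                          effects=effects, links=links)


class CohortConfig(BaseModel):
    n_patients: int = Field(default=21, ge=2)
    n_controls: int = Field(default=17, ge=2)
    epoch_samples: int = Field(default=4096, ge=256)
    n_epochs_simulated: int = Field(default=5, ge=2)
    fs: float = Field(default=625.0, gt=0)
    sensor_snr: float = Field(default=5.0, gt=0)
    effect: EffectConfig = EffectConfig()


class BeamformerConfig(BaseModel):
    reg_fraction: float = Field(default=0.05, ge=0)


class ConnectivityConfig(BaseModel):
    n_epochs: int = Field(default=5, ge=1)
    edge_trim: bool = True


class StatsConfig(BaseModel):
    n_perm: int = Field(default=5000, ge=20)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    correction: str = "none"
    outlier_rule: str = "none"  # "none" | "resid3"


class StudyConfig(BaseModel):
    """Resolved configuration of a full study run."""

    seed: int = 0
    level: str = "sensor"  # "sensor" (beamformed) or "source" (no forward)
    bands: list[str] = Field(
        default_factory=lambda: [b.name for b in CANONICAL_BANDS])
    geometry: GeometryConfig = GeometryConfig()
    cohort: CohortConfig = CohortConfig()
    beamformer: BeamformerConfig = BeamformerConfig()
    connectivity: ConnectivityConfig = ConnectivityConfig()
    stats: StatsConfig = StatsConfig()
    rsns: dict[str, list[str]] | None = None  # None -> shipped defaults

    def band_objs(self):
        return [get_band(name) for name in self.bands]

    def resolved_rsns(self) -> dict[str, list[str]]:
        return dict(self.rsns) if self.rsns is not None else dict(DEFAULT_RSNS)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(),
                                             sort_keys=True))


def _log(out_dir: Path, message: str) -> None:
    with open(out_dir / "run_log.txt", "a") as f:
        f.write(message + "\n")


def stage_simulate(config: StudyConfig, out_dir) -> None:
    """Generate geometry, cohort recordings and covariates on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = config.geometry
    geometry = generate_geometry(
        g.n_channels, g.n_rois, g.voxels_per_roi, seed=config.seed,
        head_radius=g.head_radius, sensor_radius=g.sensor_radius,
        roi_shell_radius=g.roi_shell_radius,
        cluster_radius=g.cluster_radius)
    sensors, head, atlas = geometry
    write_sensors_csv(sensors, out / "sensors.csv")
    write_atlas_json(atlas, out / "atlas.json", head)
    write_rsns_json(config.resolved_rsns(), out / "rsns.json")
    _log(out, f"simulate: {sensors.n_channels} channels, "
              f"{atlas.n_rois} ROIs, {atlas.n_voxels} voxels")

    rec_path = out / "recordings.h5"
    src_path = out / "roi_sources.h5"
    for p in (rec_path, src_path):
        if p.exists():
            p.unlink()

    c = config.cohort
    records = []
    for record, sim, rec in iter_cohort(
            c.n_patients, c.n_controls, c.effect.to_spec(), config.seed,
            rsns=config.resolved_rsns(), geometry=geometry,
            bands=config.band_objs(), n_epochs=c.n_epochs_simulated,
            epoch_samples=c.epoch_samples, fs=c.fs,
            sensor_snr=c.sensor_snr, level=config.level):
        records.append(record)
        if config.level == "sensor":
            append_recording_h5(rec, record.subject_id, rec_path)
        else:
            with h5py.File(src_path, "a") as f:
                grp = f.create_group(record.subject_id)
                grp.create_dataset("source", data=sim.signals)
                grp.attrs["fs"] = sim.fs
        _log(out, f"simulate: subject {record.subject_id} ({record.group}), "
                  f"{c.n_epochs_simulated} epochs")
    write_covariates_tsv(covariates_frame(records), out / "covariates.tsv")


def stage_beamform(config: StudyConfig, out_dir) -> None:
    """Broadband covariance, SAM weights, voxel reconstruction and per-band
    ROI voxel selection for every subject."""
    out = Path(out_dir)
    from .io import read_atlas_json, read_sensors_csv

    sensors = read_sensors_csv(out / "sensors.csv")
    atlas, head = read_atlas_json(out / "atlas.json")
    recordings = read_recordings_h5(out / "recordings.h5")
    bands = config.band_objs()
    series_path = out / "roi_series.h5"
    weights_path = out / "beamformer.h5"
    for p in (series_path, weights_path):
        if p.exists():
            p.unlink()
    positions, _ = atlas.stacked()
    for sid in sorted(recordings):
        rec = recordings[sid]
        C = compute_covariance(rec)
        model = compute_weights(positions, C, sensors, head,
                                reg_fraction=config.beamformer.reg_fraction)
        write_beamformer_h5(model.weights, model.covariance, weights_path,
                            subject_id=sid)
        vox = reconstruct_voxels(rec, model)
        with h5py.File(series_path, "a") as f:
            grp = f.create_group(sid)
            grp.attrs["fs"] = rec.fs
            for band in bands:
                grp.create_dataset(
                    band.name, data=roi_band_series(vox, atlas, band, rec.fs))
        _log(out, f"beamform: subject {sid}, {model.n_voxels} voxels, "
                  f"max unit-gain error {model.unit_gain_error().max():.2e}")


def stage_connect(config: StudyConfig, out_dir) -> None:
    """PLI adjacency per subject and band, plus summary tables."""
    out = Path(out_dir)
    from .io import read_atlas_json

    atlas, _ = read_atlas_json(out / "atlas.json")
    rsns = read_rsns_json(out / "rsns.json", atlas.labels)
    bands = config.band_objs()
    adj_dir = out / "adjacency"
    adj_dir.mkdir(exist_ok=True)

    series_path = out / "roi_series.h5"
    source_path = out / "roi_sources.h5"
    if series_path.exists():
        path, per_band = series_path, True
    elif source_path.exists():
        path, per_band = source_path, False
    else:
        raise FileNotFoundError("no roi_series.h5 or roi_sources.h5; run "
                                "the beamform (or simulate) stage first")

    sum_rows, node_rows = [], []
    with h5py.File(path, "r") as f:
        for sid in sorted(f):
            grp = f[sid]
            fs = float(grp.attrs["fs"])
            for band in bands:
                series = grp[band.name if per_band else "source"][()]
                A = adjacency(series, atlas.labels, band, fs,
                              n_epochs=config.connectivity.n_epochs,
                              subject_id=sid,
                              edge_trim=config.connectivity.edge_trim)
                write_adjacency_csv(A, adj_dir / f"{sid}_{band.name}.csv")
                sum_rows.append((sid, band.name, "whole_brain",
                                 whole_brain_mean(A)))
                for rsn_name, members in rsns.items():
                    sum_rows.append((sid, band.name, f"rsn:{rsn_name}",
                                     rsn_mean_pli(A, members)))
                for lab, s in zip(A.labels, node_strength(A)):
                    node_rows.append((sid, band.name, lab, s))
            _log(out, f"connect: subject {sid}, "
                      f"{config.connectivity.n_epochs} epochs used")

    write_results_tsv(pd.DataFrame(
        sum_rows, columns=["subject", "band", "scope", "pli"]),
        out / "summaries.tsv")
    write_results_tsv(pd.DataFrame(
        node_rows, columns=["subject", "band", "roi", "strength"]),
        out / "node_strength.tsv")


_CORR_COVARIATES = ("edss", "cognition_z", "thalamic_volume", "nbv", "ngmv")
_VOLUME_COVARIATES = ("thalamic_volume", "nbv", "ngmv")


def statistics_battery(summaries: pd.DataFrame, nodes: pd.DataFrame,
                       covariates: pd.DataFrame, *, alpha: float = 0.05,
                       n_perm: int = 5000, seed: int = 0,
                       correction: str = "none",
                       outlier_rule: str = "none") -> pd.DataFrame:
    """The full statistical battery over connectivity summary tables.

    Returns a tidy table (test, band, scope, group, covariate, statistic,
    p, n1, n2, direction, note).  ``n1`` counts patients, ``n2`` controls.
    """
    covariates = covariates.copy()
    patients = covariates.index[covariates["group"] == "patient"]
    controls = covariates.index[covariates["group"] == "control"]
    rows: list[dict] = []

    def add(test, band, scope, statistic, p, n1, n2, direction="",
            group="", covariate="", note=""):
        rows.append(dict(test=test, band=band, scope=scope, group=group,
                         covariate=covariate, statistic=statistic, p=p,
                         n1=n1, n2=n2, direction=direction, note=note))

    def correlate(band: str, scope: str, values: pd.Series) -> None:
        for grp_name, members in (("patient", patients),
                                  ("control", controls)):
            v = values.loc[members]
            for cov in _CORR_COVARIATES:
                c = covariates.loc[members, cov]
                if np.ptp(c.to_numpy()) == 0 or np.ptp(v.to_numpy()) == 0:
                    continue  # e.g. EDSS in controls
                rho, p = spearman(v.to_numpy(), c.to_numpy())
                add("spearman", band, scope, rho, p, len(v), 0,
                    group=grp_name, covariate=cov)
                if outlier_rule == "resid3":
                    x_k, y_k, dropped = discard_outliers(
                        c.to_numpy(), v.to_numpy())
                    if dropped and len(x_k) >= 5 and np.ptp(x_k) > 0:
                        rho2, p2 = spearman(y_k, x_k)
                        add("spearman_no_outliers", band, scope, rho2, p2,
                            len(x_k), 0, group=grp_name, covariate=cov,
                            note=f"discarded={dropped}")

    for cov in _VOLUME_COVARIATES:
        for grp_name, members in (("patient", patients),
                                  ("control", controls)):
            x = covariates.loc[members, cov].to_numpy()
            if len(x) >= 5 and np.ptp(x) > 0:
                stat, p = ks_normality(x)
                add("ks_normality", "", "covariate", stat, p, len(x), 0,
                    group=grp_name, covariate=cov)

    bands = list(dict.fromkeys(summaries["band"]))
    wb = summaries[summaries["scope"] == "whole_brain"].set_index(
        ["subject", "band"])["pli"]
    for band in bands:
        wb_band = wb.xs(band, level="band")
        x = wb_band.loc[patients].to_numpy()
        y = wb_band.loc[controls].to_numpy()
        cmp_wb = mann_whitney(x, y)
        direction = {"higher_in_x": "higher_in_patients",
                     "lower_in_x": "lower_in_patients",
                     "equal": "equal"}[cmp_wb.direction]
        add("mann_whitney", band, "whole_brain", cmp_wb.statistic_u,
            cmp_wb.p_value, cmp_wb.n1, cmp_wb.n2, direction=direction)
        if cmp_wb.p_value >= alpha:
            continue

        # post-hoc per-ROI permutation tests
        band_nodes = nodes[nodes["band"] == band].pivot(
            index="subject", columns="roi", values="strength")
        order = list(patients) + list(controls)
        band_nodes = band_nodes.loc[order]
        labels = np.array(["patient"] * len(patients)
                          + ["control"] * len(controls))
        perm = permutation_roi_test(band_nodes.to_numpy(), labels,
                                    n_perm=n_perm, seed=seed,
                                    correction=correction)
        for roi, t_val, p_val in zip(band_nodes.columns, perm.per_roi_t,
                                     perm.per_roi_p):
            add("permutation_t", band, f"roi:{roi}", t_val, p_val,
                len(patients), len(controls),
                direction="higher_in_patients" if t_val > 0
                else "lower_in_patients",
                note=f"n_perm={perm.n_permutations};"
                     f"correction={perm.corrected}")

        # whole-brain correlations for gated bands
        correlate(band, "whole_brain", wb.xs(band, level="band"))

        # within-RSN group tests
        rsn_scopes = sorted({s for s in summaries["scope"]
                             if s.startswith("rsn:")})
        sub = summaries.set_index(["subject", "band", "scope"])["pli"]
        for scope in rsn_scopes:
            values = sub.xs((band, scope), level=("band", "scope"))
            xr = values.loc[patients].to_numpy()
            yr = values.loc[controls].to_numpy()
            cmp_rsn = mann_whitney(xr, yr)
            direction = {"higher_in_x": "higher_in_patients",
                         "lower_in_x": "lower_in_patients",
                         "equal": "equal"}[cmp_rsn.direction]
            add("mann_whitney", band, scope, cmp_rsn.statistic_u,
                cmp_rsn.p_value, cmp_rsn.n1, cmp_rsn.n2,
                direction=direction)
            if cmp_rsn.p_value < alpha:
                correlate(band, scope, values)
                for cov in _VOLUME_COVARIATES:
                    order_all = list(patients) + list(controls)
                    y_all = values.loc[order_all].to_numpy()
                    vol = covariates.loc[order_all, cov].to_numpy()
                    grp_all = covariates.loc[order_all, "group"].to_numpy()
                    try:
                        em = effect_modification_regression(
                            y_all, vol, grp_all)
                    except ValueError:
                        continue
                    add("effect_modification", band, scope,
                        em.interaction_coef, em.interaction_p,
                        len(patients), len(controls), covariate=cov,
                        note=(f"B_{em.groups[0]}={em.slope_group1:.4g},"
                              f"beta={em.beta_group1:.3g},"
                              f"p={em.p_group1:.3g};"
                              f"B_{em.groups[1]}={em.slope_group2:.4g},"
                              f"beta={em.beta_group2:.3g},"
                              f"p={em.p_group2:.3g}"))

    return pd.DataFrame(rows, columns=["test", "band", "scope", "group",
                                       "covariate", "statistic", "p", "n1",
                                       "n2", "direction", "note"])


def stage_stats(config: StudyConfig, out_dir) -> pd.DataFrame:
    out = Path(out_dir)
    summaries = pd.read_csv(out / "summaries.tsv", sep="\t")
    nodes = pd.read_csv(out / "node_strength.tsv", sep="\t")
    covariates = read_covariates_tsv(out / "covariates.tsv")
    tests = statistics_battery(
        summaries, nodes, covariates, alpha=config.stats.alpha,
        n_perm=config.stats.n_perm, seed=config.seed,
        correction=config.stats.correction,
        outlier_rule=config.stats.outlier_rule)
    write_results_tsv(tests, out / "tests.tsv")
    _log(out, f"stats: {len(tests)} test rows")
    return tests


@dataclass
class StudyResult:
    summaries: pd.DataFrame
    node_strengths: pd.DataFrame
    tests: pd.DataFrame
    covariates: pd.DataFrame
    provenance: dict

    def digest(self) -> str:
        h = hashlib.sha256()
        for df in (self.summaries, self.node_strengths, self.tests,
                   self.covariates):
            h.update(df.round(12).to_csv().encode())
        return h.hexdigest()


def run_study(config: StudyConfig, out_dir) -> StudyResult:
    """Execute all stages in order and collect the result tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    _log(out, f"run: seed={config.seed} "
              f"config_hash={config.config_hash()} version={__version__}")

    stages = [("simulate", stage_simulate)]
    if config.level == "sensor":
        stages.append(("beamform", stage_beamform))
    stages += [("connect", stage_connect), ("stats", stage_stats)]
    for name, fn in stages:
        try:
            fn(config, out)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err

    result = StudyResult(
        summaries=pd.read_csv(out / "summaries.tsv", sep="\t"),
        node_strengths=pd.read_csv(out / "node_strength.tsv", sep="\t"),
        tests=pd.read_csv(out / "tests.tsv", sep="\t"),
        covariates=read_covariates_tsv(out / "covariates.tsv"),
        provenance={"seed": config.seed,
                    "config_hash": config.config_hash(),
                    "version": __version__})
    result.provenance["digest"] = result.digest()
    (out / "provenance.json").write_text(
        json.dumps(result.provenance, indent=1))
    return result
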