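"""Replicate-cohort studies: detection power, specificity, calibration.

These routines re-run the cohort generator many times and push each
replicate through the connectivity summaries and the gated statistical
hierarchy, measuring (i) how often the implanted band/network effects are
detected, (ii) how often non-implanted combinations reject (specificity),
(iii) how well the implanted covariate link strength is recovered as a
Spearman correlation, and (iv) the type-I error of the group tests on
null cohorts.

Replicates run on the generator's ground-truth phases (no forward/inverse
step) with shortened epochs: this keeps replicate studies tractable and is
conservative for power, since shorter epochs only make the PLI estimates
noisier.  The full-length, sensor-level path is exercised elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import ALPHA2, BETA, CANONICAL_BANDS
from .cohort import EffectSpec, default_effect_spec, iter_cohort, \
    null_effect_spec
from .connectivity import adjacency_from_phases, node_strength, \
    rsn_mean_pli, whole_brain_mean
from .geometry import generate_geometry
from .rsn import DEFAULT_RSNS
from .stats import mann_whitney, permutation_roi_test, spearman


@dataclass
class DetectionSummary:
    detection_rates: dict          # implanted (band, rsn) -> rejection rate
    false_positive_rates: dict     # non-implanted (band, rsn) -> rate
    pooled_false_positive_rate: float
    spearman_rhos: list            # per replicate: patients, thal vs PLI
    n_replicates: int

    @property
    def mean_spearman(self) -> float:
        return float(np.mean(self.spearman_rhos))


def replicate_detection_study(
    n_replicates: int = 50,
    seed: int = 0,
    *,
    effect_spec: EffectSpec | None = None,
    n_patients: int = 21,
    n_controls: int = 17,
    epoch_samples: int = 1024,
    n_epochs: int = 5,
    alpha: float = 0.05,
    bands=CANONICAL_BANDS,
    rsns: dict | None = None,
) -> DetectionSummary:
    """Detection power and specificity of the gated group tests.

    Each replicate generates a fresh default-size cohort, computes PLI
    adjacency from the simulated phases, applies the whole-brain gate per
    band, then within-network group tests (uncorrected); the implanted
    combinations' rejection rates and all others' false-positive rates are
    tallied.  The Spearman correlation between patients' thalamic volume
    and alpha2 visual-network PLI is recorded per replicate.
    """
    spec = effect_spec if effect_spec is not None else default_effect_spec()
    rsns = dict(rsns if rsns is not None else DEFAULT_RSNS)
    geometry = generate_geometry(8, 78, 1, seed=0)
    implanted = {(e.band, e.rsn) for e in spec.effects
                 if e.control_kappa != e.patient_kappa}

    det = {k: 0 for k in implanted}
    fp: dict = {}
    rhos = []
    for rep in range(n_replicates):
        wb = {b.name: {"patient": [], "control": []} for b in bands}
        rs = {(b.name, r): {"patient": [], "control": []}
              for b in bands for r in rsns}
        thal, vis = [], []
        for rec, sim, _ in iter_cohort(
                n_patients, n_controls, spec, seed * 100_000 + rep,
                geometry=geometry, rsns=rsns, bands=bands,
                epoch_samples=epoch_samples, n_epochs=n_epochs,
                level="phases"):
            for b in bands:
                A = adjacency_from_phases(sim.phases[b.name], sim.labels, b)
                wb[b.name][rec.group].append(whole_brain_mean(A))
                for r, members in rsns.items():
                    rs[(b.name, r)][rec.group].append(
                        rsn_mean_pli(A, members))
                if (rec.group == "patient" and b is ALPHA2
                        and "visual" in rsns):
                    thal.append(rec.thalamic_volume)
                    vis.append(rsn_mean_pli(A, rsns["visual"]))
        for b in bands:
            gate = mann_whitney(wb[b.name]["patient"],
                                wb[b.name]["control"]).p_value < alpha
            for r in rsns:
                sig = False
                if gate:
                    sig = mann_whitney(
                        rs[(b.name, r)]["patient"],
                        rs[(b.name, r)]["control"]).p_value < alpha
                key = (b.name, r)
                if key in implanted:
                    det[key] += sig
                else:
                    fp[key] = fp.get(key, 0) + sig
        if thal:
            rhos.append(spearman(vis, thal)[0])

    det_rates = {k: v / n_replicates for k, v in det.items()}
    fp_rates = {k: v / n_replicates for k, v in fp.items()}
    pooled = (float(np.mean(list(fp_rates.values())))
              if fp_rates else 0.0)
    return DetectionSummary(det_rates, fp_rates, pooled, rhos, n_replicates)


@dataclass
class CalibrationSummary:
    mw_p_values: list = field(default_factory=list)
    perm_p_values: list = field(default_factory=list)
    n_replicates: int = 0

    def rejection_rate(self, which: str, alpha: float = 0.05) -> float:
        p = {"mann_whitney": self.mw_p_values,
             "permutation": self.perm_p_values}[which]
        return float(np.mean(np.asarray(p) < alpha))

    @staticmethod
    def binomial_ci(alpha: float, n: int, level: float = 0.99):
        z = {0.99: 2.5758}[level]
        half = z * np.sqrt(alpha * (1 - alpha) / n)
        return alpha - half, alpha + half


def null_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    *,
    n_patients: int = 21,
    n_controls: int = 17,
    n_rois: int = 12,
    epoch_samples: int = 256,
    n_perm: int = 1000,
) -> CalibrationSummary:
    """Type-I error of the group tests on generator null cohorts.

    Cohorts carry identical baseline coupling in both groups (no implanted
    effect) on a reduced atlas; per replicate one Mann-Whitney p (whole-
    brain alpha2) and one permutation-test p (first ROI, alpha2 node
    strengths) are recorded.
    """
    geometry = generate_geometry(8, n_rois, 1, seed=1)
    atlas = geometry[2]
    half = n_rois // 2
    rsns = {"net_a": list(atlas.labels[:half]),
            "net_b": list(atlas.labels[half:])}
    bands = (ALPHA2, BETA)
    out = CalibrationSummary(n_replicates=n_replicates)
    for rep in range(n_replicates):
        wb, strengths, groups = [], [], []
        for rec, sim, _ in iter_cohort(
                n_patients, n_controls, null_effect_spec(),
                seed * 100_000 + rep, geometry=geometry, rsns=rsns,
                bands=bands, epoch_samples=epoch_samples, level="phases"):
            A = adjacency_from_phases(sim.phases["alpha2"], sim.labels,
                                      ALPHA2)
            wb.append((rec.group, whole_brain_mean(A)))
            strengths.append(node_strength(A))
            groups.append(rec.group)
        x = [v for g, v in wb if g == "patient"]
        y = [v for g, v in wb if g == "control"]
        out.mw_p_values.append(mann_whitney(x, y).p_value)
        res = permutation_roi_test(np.asarray(strengths),
                                   np.asarray(groups), n_perm=n_perm,
                                   seed=rep)
        out.perm_p_values.append(float(res.per_roi_p[0]))
    return out
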