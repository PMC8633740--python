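"""End-to-end orchestration: configuration, stage sequencing, and I/O.

Stage order: synthesize (or ingest) -> denoise -> consensus networks from
placebo scans only -> dual regression of both conditions against those
networks (within-network TFCE permutation contrasts) -> between-network
Fisher-z / NBS contrasts -> behavioral analysis and brain-behavior
correlation.  Every stage's randomness descends from the single study seed,
so identical configurations reproduce identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behav, betweennet, denoise, dualreg, metagica, synthdata
from .core import (BoldSession, config_hash, save_maps_nifti,
                   save_session_nifti, spawn_seeds)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "ResultsBundle", "run_full"]


@dataclass
class StudyConfig:
    """All pipeline parameters.

    Defaults are the reference settings of the analysis: motion threshold
    0.5 mm, global-signal threshold 3 SD, drift order 2, passband
    0.008-0.09 Hz, smoothing FWHM 6 mm, 10 ICA runs matched at |r| > 0.7
    with relaxed support 4, 5000 permutations per GLM, NBS edge gate
    P < 0.01 with component threshold P < 0.05, familywise alpha 0.05.
    """

    seed: int = 0
    out_dir: str | None = None

    # synthesis (ignored when data_dir is given)
    n_subjects: int = 22
    tr_seconds: float = 3.0
    n_volumes: int = 124
    n_networks: int = 8
    grid_shape: tuple[int, int, int] = synthdata.DEFAULT_GRID
    noise_sd: float = 0.5
    subject_sd: float = 0.05
    spike_prob: float = 0.05
    hub_scenario: bool = False
    hub_effect: float = 0.2

    # denoising
    fd_thresh_mm: float = 0.5
    gs_thresh_sd: float = 3.0
    drift_order: int = 2
    band_hz: tuple[float, float] = (0.008, 0.09)
    fwhm_mm: float = 6.0
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    # consensus networks
    n_ica_runs: int = 10
    match_threshold: float = 0.7
    relaxed_support: int = 4
    max_model_order: int = 20
    model_order: int | None = None

    # within-network inference
    n_perm_within: int = 5000
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_connectivity: int = 26
    familywise_alpha: float = 0.05

    # between-network inference
    edge_p: float = 0.01
    component_alpha: float = 0.05
    n_perm_between: int = 5000

    # ratings
    rating_measures: tuple[str, ...] = ("arci_a", "heart_rate")
    drug_effect_size: float = 3.0
    rating_noise_sd: float = 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "band_hz", "voxel_size_mm",
                    "rating_measures"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def study_spec(self) -> synthdata.StudySpec:
        if self.hub_scenario:
            corr, delta = synthdata.hub_scenario_deltas(
                self.n_networks, effect=self.hub_effect)
        else:
            corr, delta = None, None
        return synthdata.StudySpec(
            n_subjects=self.n_subjects, tr_seconds=self.tr_seconds,
            n_volumes=self.n_volumes, n_networks=self.n_networks,
            edge_corr_placebo=corr, edge_delta_drug=delta,
            noise_sd=self.noise_sd, subject_sd=self.subject_sd,
            spike_prob=self.spike_prob, seed=self.seed,
            grid_shape=tuple(self.grid_shape))


@dataclass
class ResultsBundle:
    """Structured outputs of a full run with provenance."""

    consensus: metagica.ConsensusNetworkSet
    within_results: list[dualreg.VoxelContrastResult]
    cluster_table: pd.DataFrame
    pair_table: pd.DataFrame
    edge_result: betweennet.EdgeContrastResult
    anova: dict[str, behav.AnovaResult]
    pcs: behav.PeakChangeScores
    behavior_correlations: pd.DataFrame
    ratings: pd.DataFrame
    excluded_subjects: list[str]
    provenance: dict

    def write(self, out_dir: str | Path,
              voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.consensus.n_networks:
            save_maps_nifti(self.consensus.maps(), out / "consensus.nii.gz",
                            voxel_size_mm)
        sidecar = [{"label": n.label, "support": n.support,
                    "members": [list(m) for m in n.members],
                    "artifact": bool(n.artifact_flag)}
                   for n in self.consensus.networks]
        (out / "consensus.json").write_text(json.dumps(sidecar, indent=2))
        self.cluster_table.to_csv(out / "within_clusters.tsv", sep="\t",
                                  index=False)
        self.pair_table.to_csv(out / "between_pairs.tsv", sep="\t",
                               index=False)
        anova_rows = []
        for measure, res in self.anova.items():
            for eff, d in res.effects.items():
                anova_rows.append({"measure": measure, "effect": eff,
                                   "F": d["F"], "df1": d["df"][0],
                                   "df2": d["df"][1], "p": d["p"]})
        pd.DataFrame(anova_rows).to_csv(out / "anova.tsv", sep="\t",
                                        index=False)
        self.behavior_correlations.to_csv(out / "behavior_correlations.tsv",
                                          sep="\t", index=False)
        self.ratings.to_csv(out / "ratings.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.provenance, indent=2, default=str))


def _cluster_table(results: list[dualreg.VoxelContrastResult],
                   labels: list[str]) -> pd.DataFrame:
    rows = []
    for res in results:
        for cl in res.significant_clusters:
            peak = cl["voxels"][0]
            rows.append({
                "network": labels[res.network_id],
                "direction": cl["direction"],
                "size": cl["size"],
                "peak_voxel": ",".join(str(int(v)) for v in peak),
                "peak_p": cl["peak_p"]})
    return pd.DataFrame(rows, columns=["network", "direction", "size",
                                       "peak_voxel", "peak_p"])


def run_full(config: StudyConfig,
             bundle: synthdata.StudyBundle | None = None) -> ResultsBundle:
    """Run the complete analysis on a synthetic (or supplied) study."""
    seeds = spawn_seeds(config.seed, 6)
    stage = "synthesize"
    try:
        if bundle is None:
            bundle = synthdata.simulate_paired_study(config.study_spec())
        subjects = bundle.subjects

        stage = "denoise"
        # smoothing is held back from the ICA input (network identification
        # on unsmoothed residuals keeps the Laplace order estimate's
        # independent-voxel assumption tenable) and applied to the sessions
        # entering the voxelwise dual-regression contrast
        denoised: dict[tuple[str, str], BoldSession] = {}
        smoothed: dict[tuple[str, str], BoldSession] = {}
        fd_by_subject: dict[str, dict[str, np.ndarray]] = {}
        for (sid, cond), sess in bundle.sessions.items():
            den, conf = denoise.denoise_session(
                sess, fd_thresh=config.fd_thresh_mm,
                gs_thresh=config.gs_thresh_sd,
                drift_order=config.drift_order, band_hz=tuple(config.band_hz),
                fwhm_mm=0.0)
            denoised[(sid, cond)] = den
            smoothed[(sid, cond)] = (
                denoise.smooth(den, config.fwhm_mm,
                               tuple(config.voxel_size_mm))
                if config.fwhm_mm > 0 else den)
            fd_by_subject.setdefault(sid, {})[cond] = conf.fd_series
        excluded = []
        for sid in subjects:
            bad, reason = denoise.subject_exclusion(
                fd_by_subject[sid], fd_thresh=config.fd_thresh_mm)
            if bad:
                logger.info("excluding subject %s: %s", sid, reason)
                excluded.append(sid)
        kept = [s for s in subjects if s not in excluded]
        if len(kept) < 3:
            raise RuntimeError("fewer than 3 subjects retained")

        stage = "consensus networks"
        placebo_sessions = [denoised[(s, "placebo")] for s in kept]
        runs = metagica.run_meta_gica(
            placebo_sessions, n_runs=config.n_ica_runs, master_seed=seeds[0],
            max_order=config.max_model_order, order=config.model_order)
        mask = placebo_sessions[0].mask
        graph = metagica.cross_correlate_runs(runs, mask,
                                              config.match_threshold)
        consensus = metagica.extract_consensus(graph, n_runs=len(runs),
                                               runs=runs, mask=mask)
        used = {m for n in consensus.networks for m in n.members}
        extra = metagica.relaxed_consensus(graph,
                                           min_support=config.relaxed_support,
                                           exclude=used, runs=runs, mask=mask)
        consensus.networks.extend(extra.networks)
        metagica.flag_artifact_components(consensus, mask)
        labels = consensus.labels(include_artifacts=False)
        if not labels:
            raise RuntimeError("no consensus networks identified")

        stage = "dual regression"
        dr: dict[tuple[str, str], dualreg.SubjectNetworkMaps] = {}
        for sid in kept:
            for cond in ("placebo", "drug"):
                dr[(sid, cond)] = dualreg.dual_regression(
                    smoothed[(sid, cond)], consensus)
        K = len(labels)

        stage = "within-network inference"
        params = dualreg.TfceParams(E=config.tfce_E, H=config.tfce_H,
                                    connectivity=config.tfce_connectivity)
        drug_maps = [dr[(s, "drug")] for s in kept]
        pl_maps = [dr[(s, "placebo")] for s in kept]
        within = []
        for k in range(K):
            diffs, _ = dualreg.paired_differences(drug_maps, pl_maps, k, mask)
            res = dualreg.permutation_inference(
                diffs, mask, params, n_perm=config.n_perm_within,
                seed=seeds[1] + k, network_id=k)
            within.append(res)
        dualreg.bonferroni_gate(within, config.familywise_alpha,
                                n_tests=K * 2,
                                connectivity=config.tfce_connectivity)
        cluster_table = _cluster_table(within, labels)

        stage = "between-network inference"
        edge_mats = {}
        for (sid, cond), maps in dr.items():
            edge_mats[(sid, cond)] = betweennet.edge_matrix(
                maps.timecourses, subject_id=sid, condition=cond,
                labels=labels)
        z_diffs = np.stack([edge_mats[(s, "drug")].z
                            - edge_mats[(s, "placebo")].z for s in kept])
        edge_result = betweennet.network_level_inference(
            z_diffs, edge_p=config.edge_p,
            component_alpha=config.component_alpha,
            n_perm=config.n_perm_between, seed=seeds[2], labels=labels)
        pair_table = betweennet.report_pairs(edge_result)

        stage = "behavioral analysis"
        schedule = synthdata.RatingsSchedule(
            measures=tuple(config.rating_measures),
            drug_effect_size={m: config.drug_effect_size
                              for m in config.rating_measures},
            within_subject_sd=config.rating_noise_sd)
        ratings = synthdata.simulate_ratings(schedule, len(kept),
                                             seed=seeds[3])
        anova = {m: behav.rm_anova(ratings, m)
                 for m in config.rating_measures}
        pcs = behav.peak_change_score(ratings, config.rating_measures[0])

        fc_deltas: dict[str, np.ndarray] = {}
        for comp in edge_result.components:
            for i, j in comp["edges"]:
                i, j = (i, j) if i < j else (j, i)
                name = f"edge_{labels[i]}-{labels[j]}"
                fc_deltas[name] = z_diffs[:, i, j]
        for res in within:
            for ci, cl in enumerate(res.significant_clusters):
                vox = tuple(cl["voxels"].T)
                vals = np.stack([res.diff_maps[s][vox].mean()
                                 for s in range(res.diff_maps.shape[0])])
                fc_deltas[f"cluster_{labels[res.network_id]}_{ci}"] = vals
        y = pcs.delta.to_numpy()
        fc_deltas = {k: v for k, v in fc_deltas.items() if len(v) == len(y)}
        corr_table = behav.fc_behavior_correlation(fc_deltas, y) \
            if fc_deltas else pd.DataFrame(
                columns=["fc_measure", "r", "p_raw", "p_bonferroni",
                         "significant"])
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    provenance = {
        "config": config.to_dict(),
        "config_hash": config_hash(config.to_dict()),
        "seed": config.seed, "stage_seeds": seeds,
        "n_subjects_retained": len(kept),
        "excluded_subjects": excluded,
        "n_consensus_networks": consensus.n_networks,
        "n_networks_tested": K,
    }
    result = ResultsBundle(
        consensus=consensus, within_results=within,
        cluster_table=cluster_table, pair_table=pair_table,
        edge_result=edge_result, anova=anova, pcs=pcs,
        behavior_correlations=corr_table, ratings=ratings,
        excluded_subjects=excluded, provenance=provenance)
    if config.out_dir:
        result.write(config.out_dir, tuple(config.voxel_size_mm))
    return result


# ---------------------------------------------------------------------------
# workspace I/O used by the CLI

def write_study(bundle: synthdata.StudyBundle, out_dir: str | Path,
                ratings: pd.DataFrame | None = None,
                voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    """Write a simulated study to disk: NIfTI sessions, mask, motion tables,
    ground-truth maps/edges, and the ratings CSV."""
    out = Path(out_dir)
    (out / "sessions").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    import nibabel as nib
    aff = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(bundle.truth.mask.astype(np.uint8), aff),
             str(out / "mask.nii.gz"))
    save_maps_nifti(bundle.truth.maps, out / "truth" / "maps.nii.gz",
                    voxel_size_mm)
    for (sid, cond), sess in bundle.sessions.items():
        stem = f"{sid}_{cond}"
        save_session_nifti(sess, out / "sessions" / f"{stem}.nii.gz",
                           voxel_size_mm)
        if sess.motion_params is not None:
            np.savetxt(out / "sessions" / f"{stem}_motion.txt",
                       sess.motion_params, fmt="%.6f")
        pd.DataFrame(bundle.edge_truth[(sid, cond)]).to_csv(
            out / "truth" / f"edges_{stem}.csv", index=False)
    if ratings is not None:
        ratings.to_csv(out / "ratings.csv", index=False)
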