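"""End-to-end orchestration of the synthetic-activation analysis.

Stages run in dependency order — data generation, group statistics, unit
selection, decoder training, the comparison task, embedding scoring with the
superior/inferior split, and RSA — each writing its artifacts (CSV tables,
JSON reports, binary array containers with JSON sidecars) under the output
directory with provenance (config hash, seed, library versions). Completed
stages are skipped on rerun when the config hash matches, so a run is
resumable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import spawn_seeds
from .activations import ActivationMatrix, normalize_unit_range
from .comparison import PsychCurve, curve_tests, percent_correct, psychometric, run_comparison
from .config import RunConfig
from .decoder import DecoderModel, select_monotone_units, train_decoder
from .embedding import score_rows, split_subsets
from .group_stats import decile_stats, resample_summary, trend_tests
from .rsa import compare_rsms, rsm_from_curves
from .synth import gen_activation_dataset

__all__ = ["run_pipeline"]

log = logging.getLogger("numsense")


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(yaml.safe_dump(asdict(cfg), sort_keys=True)
                          .encode()).hexdigest()[:16]


def _provenance(cfg: RunConfig) -> dict:
    import sklearn
    import scipy
    return {"config_hash": _config_hash(cfg), "seed": cfg.seed,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                         "scipy": scipy.__version__, "sklearn": sklearn.__version__}}


def _stage_done(stage_dir: Path, conf_hash: str) -> bool:
    marker = stage_dir / "DONE.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == conf_hash
    except json.JSONDecodeError:
        return False


def _mark_done(stage_dir: Path, conf_hash: str) -> None:
    (stage_dir / "DONE.json").write_text(json.dumps({"config_hash": conf_hash}))


def _mean_curve(perfs, agent, condition) -> PsychCurve:
    curves = [psychometric(p, agent=agent) for p in perfs]
    return PsychCurve(distances=curves[0].distances,
                      rates=np.mean([c.rates for c in curves], axis=0),
                      counts=np.sum([c.counts for c in curves], axis=0),
                      agent=agent, condition=condition)


def _subset_curves(decoded: np.ndarray, meta: pd.DataFrame, ids, trials: int,
                   reps: int, seed: int, condition: str):
    keep = meta["picture_id"].isin(set(ids)).to_numpy()
    pools = {int(g): decoded[keep & (meta["group"].to_numpy() == g)]
             for g in np.unique(meta["group"][keep])}
    perfs = run_comparison(pools, trials_per_cell=trials, reps=reps, seed=seed,
                           condition=condition)
    return [psychometric(p, agent="decoder") for p in perfs]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full synthetic pipeline; returns the run report dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conf_hash = _config_hash(cfg)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir, conf_hash)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, outdir: Path, conf_hash: str) -> dict:
    seeds = spawn_seeds(cfg.seed, 8)
    report: dict = {"provenance": _provenance(cfg)}
    cfg.to_yaml(outdir / "config.yaml")

    # -- stage 1: synthetic datasets --------------------------------------
    d_data = outdir / "data"
    d_data.mkdir(exist_ok=True)
    if cfg.resume and _stage_done(d_data, conf_hash):
        log.info("data: resumed from %s", d_data)
        train_raw = ActivationMatrix.load(d_data / "train")
        val_raw = ActivationMatrix.load(d_data / "val")
        profiles = None
    else:
        train_raw = gen_activation_dataset(replace(cfg.synth_train, seed=seeds[0]))
        profiles = train_raw.attrs["profiles"]
        val_raw = gen_activation_dataset(
            replace(cfg.synth_val, seed=seeds[1],
                    n_units=cfg.synth_train.n_units,
                    n_increasing=cfg.synth_train.n_increasing,
                    n_decreasing=cfg.synth_train.n_decreasing),
            profiles=profiles,
            planted_units=(train_raw.attrs["increasing_units"],
                           train_raw.attrs["decreasing_units"]))
        train_raw.save(d_data / "train")
        val_raw.save(d_data / "val")
        profiles.to_csv(d_data / "profiles.csv")
        _mark_done(d_data, conf_hash)
    if profiles is None:
        from .activations import CategoryProfileMatrix
        profiles = CategoryProfileMatrix.from_csv(d_data / "profiles.csv")
    train = normalize_unit_range(train_raw)
    val = normalize_unit_range(val_raw)
    report["data"] = {"train_pictures": train.n_pictures, "val_pictures": val.n_pictures,
                      "n_units": train.n_units}

    # -- stage 2: group statistics ----------------------------------------
    d_stats = outdir / "group_stats"
    d_stats.mkdir(exist_ok=True)
    summaries = resample_summary(train, n_pick=min(cfg.resample_n_pick,
                                                   cfg.synth_train.n_pictures_per_group),
                                 reps=cfg.resample_reps, seed=seeds[2])
    deciles = pd.concat([s.to_frame() for s in summaries], ignore_index=True)
    deciles.to_csv(d_stats / "deciles.csv", index=False)
    tests = trend_tests(summaries[0])
    tests["anova"].to_csv(d_stats / "anova.csv", index=False)
    tests["mean_posthoc"].to_csv(d_stats / "mean_posthoc.csv", index=False)
    mean90 = np.mean([decile_stats(s, "mean90") for s in summaries], axis=0)
    std10 = np.mean([decile_stats(s, "std10") for s in summaries], axis=0)
    report["group_stats"] = {
        "mean90_by_group": mean90.tolist(), "std10_by_group": std10.tolist(),
        "anova_mean_F": tests["mean"]["F"], "anova_std_F": tests["std"]["F"]}

    # -- stage 3: unit selection ------------------------------------------
    unitset = select_monotone_units(train, alpha=cfg.selection_alpha,
                                    expected_groups=range(1, cfg.synth_train.n_groups + 1))
    (outdir / "unitset.json").write_text(json.dumps({
        "increasing": unitset.increasing.tolist(),
        "decreasing": unitset.decreasing.tolist(),
        "alpha": unitset.alpha}))
    report["selection"] = {"n_increasing": int(unitset.increasing.size),
                           "n_decreasing": int(unitset.decreasing.size)}
    log.info("selection: %d increasing, %d decreasing units",
             unitset.increasing.size, unitset.decreasing.size)

    # -- stage 4: decoder ---------------------------------------------------
    d_dec = outdir / "decoder"
    d_dec.mkdir(exist_ok=True)
    if cfg.resume and _stage_done(d_dec, conf_hash):
        model = DecoderModel.load(d_dec / "model")
        log.info("decoder: resumed")
    else:
        model = train_decoder(train, unitset, cfg=replace(cfg.decoder, seed=seeds[3]))
        model.save(d_dec / "model")
        _mark_done(d_dec, conf_hash)
    from scipy import stats as sps
    decoded_val = model.decode(val)
    rho = float(sps.spearmanr(decoded_val, val.groups).statistic)
    group_means = {int(g): float(decoded_val[val.groups == g].mean())
                   for g in np.unique(val.groups)}
    pd.DataFrame({"picture_id": val.meta["picture_id"], "group": val.groups,
                  "decoded": decoded_val}).to_csv(d_dec / "decoded_val.csv", index=False)
    report["decoder"] = {"val_spearman": rho, "group_means": group_means}

    # -- stage 5: comparison task ------------------------------------------
    d_cmp = outdir / "comparison"
    d_cmp.mkdir(exist_ok=True)
    pools = {int(g): decoded_val[val.groups == g] for g in np.unique(val.groups)}
    perfs = run_comparison(pools, trials_per_cell=cfg.trials_per_cell,
                           reps=cfg.comparison_reps, seed=seeds[4], condition="val")
    perf_mean = np.mean([p.values for p in perfs], axis=0)
    pd.DataFrame(perf_mean, index=perfs[0].numbers, columns=perfs[0].numbers) \
        .to_csv(d_cmp / "performance_matrix.csv")
    curve = _mean_curve(perfs, "decoder", "val")
    curve.to_frame().to_csv(d_cmp / "psychometric.csv", index=False)
    chance = curve_tests([psychometric(p) for p in perfs])
    chance.to_csv(d_cmp / "curve_tests.csv", index=False)
    report["comparison"] = {"curve": dict(zip(curve.distances.tolist(),
                                              np.round(curve.rates, 4).tolist()))}

    # -- stage 6: embedding -------------------------------------------------
    d_emb = outdir / "embedding"
    d_emb.mkdir(exist_ok=True)
    scores = score_rows(val, profiles).rename(columns={"coefficient": "score"})
    split = split_subsets(scores, k=min(cfg.subset_k,
                                        cfg.synth_val.n_pictures_per_group // 2))
    scores["subset"] = [split.tag(p) for p in scores["picture_id"]]
    scores.to_csv(d_emb / "scores.csv", index=False)
    sup_curves = _subset_curves(decoded_val, val.meta, split.superior["picture_id"],
                                cfg.trials_per_cell_embedding, cfg.comparison_reps,
                                seeds[5], "superior")
    inf_curves = _subset_curves(decoded_val, val.meta, split.inferior["picture_id"],
                                cfg.trials_per_cell_embedding, cfg.comparison_reps,
                                seeds[5] + 1, "inferior")
    emb_tests = curve_tests(sup_curves, other=inf_curves)
    emb_tests.to_csv(d_emb / "superior_vs_inferior.csv", index=False)
    dist = sup_curves[0].distances
    far = np.abs(dist) >= 3
    pc_gap = float(np.mean([percent_correct(s)[far].mean() - percent_correct(i)[far].mean()
                            for s, i in zip(sup_curves, inf_curves)]))
    report["embedding"] = {"percent_correct_gap_far": pc_gap,
                           "superior_mean_score": float(split.superior["score"].mean()),
                           "inferior_mean_score": float(split.inferior["score"].mean())}

    # -- stage 7: RSA --------------------------------------------------------
    d_rsa = outdir / "rsa"
    d_rsa.mkdir(exist_ok=True)
    n_ref = cfg.rsa_min_references
    ref_seeds = spawn_seeds(seeds[6], 2 * (n_ref + 1))
    refs = []
    for r in range(n_ref):
        s_c = _subset_curves(decoded_val, val.meta, split.superior["picture_id"],
                             cfg.trials_per_cell_embedding, 1, ref_seeds[2 * r], "superior")[0]
        i_c = _subset_curves(decoded_val, val.meta, split.inferior["picture_id"],
                             cfg.trials_per_cell_embedding, 1, ref_seeds[2 * r + 1], "inferior")[0]
        refs.append(rsm_from_curves(s_c, i_c, agent=f"ref{r}"))
    s_c = _subset_curves(decoded_val, val.meta, split.superior["picture_id"],
                         cfg.trials_per_cell_embedding, 1, ref_seeds[-2], "superior")[0]
    i_c = _subset_curves(decoded_val, val.meta, split.inferior["picture_id"],
                         cfg.trials_per_cell_embedding, 1, ref_seeds[-1], "inferior")[0]
    cand = rsm_from_curves(s_c, i_c, agent="decoder")
    rng = np.random.default_rng(seeds[7])
    perm = rng.permutation(cand.values.shape[0])
    from .rsa import RSM
    shuffled = RSM(values=cand.values[np.ix_(perm, perm)], ids=list(cand.ids),
                   agent="shuffled", level="condition")
    rsa_report = compare_rsms(refs, [cand, shuffled], min_references=n_ref)
    rsa_report["candidates"].to_csv(d_rsa / "candidates.csv", index=False)
    cand.to_csv(d_rsa / "decoder_rsm.csv")
    report["rsa"] = {
        row["candidate"]: {"mean_correlation": row["mean_correlation"],
                           "p_fdr": row["p_fdr"], "significant": row["significant"]}
        for _, row in rsa_report["candidates"].iterrows()}

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    log.info("pipeline complete; report at %s", outdir / "report.json")
    return report
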