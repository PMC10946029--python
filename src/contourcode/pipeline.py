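"""End-to-end orchestration: features -> tuning -> MI -> population map.

Natural and silhouette stimuli of the same contour geometry share feature
values (features are computed from the silhouette contours and applied to
the natural twins), so feature tables are keyed by geometry and expanded
to stimuli here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import information, population, tuning
from .features import CurvatureParams, FeatureTable, compute_features
from .io import ResponseTable, RunConfig
from .synthetic import StimulusSet, make_population, generate_contours, \
    simulate_responses, StimulusSetConfig


def _derived_seed(base: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(base), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))


def feature_tables(stimulus_set: StimulusSet, crfs: dict,
                   cfg: RunConfig | None = None) -> FeatureTable:
    """Features per (neuron, geometry), sharing work across equal CRFs."""
    cfg = cfg or RunConfig()
    params = CurvatureParams(
        a=cfg.squash_a, window_scales=cfg.window_scales,
        slide_step=cfg.slide_step, min_points=cfg.min_points,
        error_percentile=cfg.error_percentile, max_circles=cfg.max_circles,
    )
    return compute_features(stimulus_set.contours, crfs,
                            curvature_params=params)


def _neuron_feature_arrays(features: FeatureTable, neuron_id,
                           stimulus_ids, geometry_of: pd.Series):
    """Per-stimulus feature arrays for one neuron (geometry expanded)."""
    pp = features.per_pair
    sub = pp[pp["neuron_id"] == neuron_id].set_index("stimulus_id")
    geoms = [geometry_of[s] for s in stimulus_ids]
    out = {f: np.array([sub.at[g, f] for g in geoms], dtype=float)
           for f in ("closure", "symmetry", "orientation")}
    out["n_curvatures"] = np.array([sub.at[g, "n_curvatures"]
                                    for g in geoms], dtype=int)
    lists = features.curvature_lists(neuron_id)
    out["curvature_lists"] = {s: lists.get(g, np.empty(0))
                              for s, g in zip(stimulus_ids, geoms)}
    return out


# --------------------------------------------------------------------------
# tuning stage
# --------------------------------------------------------------------------

def tuning_analysis(features: FeatureTable, responses: ResponseTable,
                    geometry_of: pd.Series,
                    cfg: RunConfig | None = None) -> pd.DataFrame:
    """Per-(neuron, feature) tuning fits and permutation significance.

    Exclusion rules: neurons with any missing curvature or orientation
    value are excluded from those features; closure retains neurons with
    partial missingness; symmetry is never missing.
    """
    cfg = cfg or RunConfig()
    bins = {"closure": cfg.closure_bins, "symmetry": cfg.symmetry_bins,
            "curvature": cfg.curvature_bins,
            "orientation": cfg.orientation_bins}
    tm = responses.trial_means()
    rows = []
    for ni, neuron_id in enumerate(tm.index):
        resp = tm.loc[neuron_id].dropna()
        stim_ids = list(resp.index)
        arrays = _neuron_feature_arrays(features, neuron_id, stim_ids,
                                        geometry_of)
        for fi, feature in enumerate(
                ("closure", "curvature", "symmetry", "orientation")):
            edges = tuning.feature_edges(feature, bins[feature])
            rec = {"neuron_id": neuron_id, "feature": feature,
                   "excluded": False, "reason": ""}
            if feature == "curvature":
                if (arrays["n_curvatures"] == 0).any():
                    rec.update(excluded=True, reason="missing curvature")
                    rows.append(rec)
                    continue
                values = arrays["curvature_lists"]
            elif feature == "orientation":
                if np.isnan(arrays["orientation"]).any():
                    rec.update(excluded=True, reason="missing orientation")
                    rows.append(rec)
                    continue
                values = arrays[feature]
            else:
                values = arrays[feature]
            try:
                map_ = tuning.build_tuning_map(
                    feature, values, resp.to_numpy(float), edges=edges,
                    stimulus_order=stim_ids)
                if map_.n_occupied < 4:
                    rec.update(excluded=True, reason="too few occupied bins")
                    rows.append(rec)
                    continue
                fit = tuning.fit_tuning(map_)
                perm = tuning.permutation_test_tuning(
                    feature, values, resp.to_numpy(float),
                    n_perm=cfg.n_perm_tuning, alpha=cfg.alpha_tuning,
                    seed=_derived_seed(cfg.seed_permutation, ni, fi),
                    edges=edges, stimulus_order=stim_ids)
            except ValueError as exc:
                rec.update(excluded=True, reason=str(exc))
                rows.append(rec)
                continue
            rec.update(fit.params, strength=fit.strength, rmse=fit.rmse,
                       optimal=fit.optimal, significant=perm.significant,
                       p=perm.p)
            rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# MI stage
# --------------------------------------------------------------------------

def mi_analysis(features: FeatureTable, responses: ResponseTable,
                geometry_of: pd.Series, tuning_df: pd.DataFrame | None = None,
                cfg: RunConfig | None = None,
                curvature_mode: str = "expand") -> dict:
    """Per-(neuron, feature) MI with weak-response exclusion, permutation
    significance, MI profiles and tuned-vs-untuned comparisons.

    ``curvature_mode="expand"`` pairs every local curvature with its
    stimulus's response (mirroring the tuning histograms);
    ``"mean"`` collapses each stimulus to its mean local curvature.
    """
    cfg = cfg or RunConfig()
    tm = responses.trial_means()
    totals = responses.df.groupby(["neuron", "stimulus"])["count"].sum()
    rows = []
    for ni, neuron_id in enumerate(tm.index):
        resp = tm.loc[neuron_id].dropna()
        stim_ids = list(resp.index)
        arrays = _neuron_feature_arrays(features, neuron_id, stim_ids,
                                        geometry_of)
        for fi, feature in enumerate(
                ("closure", "curvature", "symmetry", "orientation")):
            rec = {"neuron_id": neuron_id, "feature": feature,
                   "excluded": False, "reason": ""}
            if feature == "curvature":
                lists = arrays["curvature_lists"]
                avail = [s for s in stim_ids if len(lists[s]) > 0]
                if curvature_mode == "expand":
                    x = np.concatenate([
                        np.full(len(lists[s]), resp[s]) for s in avail
                    ]) if avail else np.empty(0)
                    y = (np.concatenate([lists[s] for s in avail])
                         if avail else np.empty(0))
                else:
                    x = resp[avail].to_numpy(float)
                    y = np.array([np.mean(lists[s]) for s in avail])
            else:
                fv = arrays[feature]
                ok = ~np.isnan(fv)
                avail = [s for s, o in zip(stim_ids, ok) if o]
                x = resp[avail].to_numpy(float)
                y = fv[ok]
            spikes = int(sum(totals.get((neuron_id, s), 0) for s in avail))
            rec["total_spikes"] = spikes
            if spikes < cfg.weak_spike_threshold:
                rec.update(excluded=True, reason="weak response")
                rows.append(rec)
                continue
            if len(x) < 4:
                rec.update(excluded=True, reason="too few data")
                rows.append(rec)
                continue
            perm = information.permutation_test_mi(
                x, y, n_perm=cfg.n_perm_mi, alpha=cfg.alpha_mi,
                seed=_derived_seed(cfg.seed_permutation, 1000 + ni, fi))
            rec.update(mi=perm.mi_obs, n=len(x),
                       nbin=information.make_binning(x, y).nbin,
                       significant=perm.significant, p=perm.p)
            rows.append(rec)
    mi_table = pd.DataFrame(rows)

    # wide table of neurons with all four MIs
    ok = mi_table[~mi_table["excluded"]]
    wide = ok.pivot_table(index="neuron_id", columns="feature", values="mi")
    wide = wide.dropna()
    profile = None
    if len(wide) >= 2:
        prof_in = pd.DataFrame({
            "neuron_id": wide.index,
            "mi_closure": wide["closure"].to_numpy(),
            "mi_curvature": wide["curvature"].to_numpy(),
            "mi_symmetry": wide["symmetry"].to_numpy(),
            "mi_orientation": wide["orientation"].to_numpy(),
        })
        profile = information.mi_profile(
            prof_in, seed=_derived_seed(cfg.seed_permutation, 999999))

    comparisons = {}
    if tuning_df is not None:
        sig = tuning_df[~tuning_df["excluded"]].set_index(
            ["neuron_id", "feature"])["significant"]
        for feature in ("closure", "curvature", "symmetry", "orientation"):
            sub = ok[ok["feature"] == feature]
            flags, mis = [], []
            for _, r in sub.iterrows():
                key = (r["neuron_id"], feature)
                if key in sig.index:
                    flags.append(bool(sig[key]))
                    mis.append(r["mi"])
            if flags and any(flags) and not all(flags):
                comparisons[feature] = information.compare_tuned_vs_untuned(
                    mis, flags)
    return {"mi_table": mi_table, "profile": profile,
            "comparisons": comparisons}


# --------------------------------------------------------------------------
# population stage
# --------------------------------------------------------------------------

def population_analysis(responses: ResponseTable, kinds: pd.Series,
                        tuning_df: pd.DataFrame,
                        cfg: RunConfig | None = None,
                        silhouette_only: bool = False) -> dict:
    """MDS map plus axis profiles and regressions.

    Neurons entering the map are those for which all four features could
    be examined (no tuning exclusions).  The primary axis is oriented so
    the number of significantly tuned features increases along it, the
    secondary axis so NS preference increases.
    """
    cfg = cfg or RunConfig()
    excl = tuning_df.groupby("neuron_id")["excluded"].any()
    eligible = [n for n in excl.index if not excl[n]]
    df = responses.df[responses.df["neuron"].isin(eligible)]
    matrix = population.build_response_matrix(df, kinds)
    if silhouette_only:
        matrix = matrix.silhouette_only()
    pm = population.run_mds(matrix, dim=2, seed=cfg.seed_mds,
                            n_restarts=cfg.mds_restarts)
    neurons = matrix.neurons

    ok = tuning_df[~tuning_df["excluded"]]
    sig = ok.pivot_table(index="neuron_id", columns="feature",
                         values="significant", aggfunc="first")
    n_sig = sig.reindex(neurons).fillna(False).astype(bool).sum(axis=1)
    ns_pref = population.ns_preferences(responses, kinds).reindex(neurons)

    coords = population.orient_axes(pm.coords, n_sig.to_numpy(float),
                                    ns_pref.to_numpy(float))
    groups = population.group_equal_count(coords, axis=0, k=cfg.n_groups)

    window = min(cfg.axis_window, len(neurons))
    profiles = {"n_significant": population.axis_profile(
        coords, 0, n_sig.to_numpy(float), window=window,
        smooth=cfg.axis_smooth)}
    for feature in ("closure", "curvature", "symmetry", "orientation"):
        if feature in sig.columns:
            flags = sig[feature].reindex(neurons).fillna(False)
            profiles[f"sig_{feature}"] = population.axis_profile(
                coords, 0, flags.to_numpy(float), window=window,
                smooth=cfg.axis_smooth)
    ns_vals = ns_pref.to_numpy(float)
    if np.isfinite(ns_vals).all():
        profiles["ns_preference"] = population.axis_profile(
            coords, 1, ns_vals, window=window, smooth=cfg.axis_smooth)

    regressions = {
        "n_significant~axis0": population.regress_axis(
            n_sig.to_numpy(float), coords, 0),
        "ns_preference~axis1": population.regress_axis(ns_vals, coords, 1),
    }
    return {"map": pm, "coords": coords, "neurons": neurons,
            "groups": groups, "n_significant": n_sig, "ns_pref": ns_pref,
            "profiles": profiles, "regressions": regressions,
            "matrix": matrix}


# --------------------------------------------------------------------------
# full synthetic study
# --------------------------------------------------------------------------

def run_study(cfg: RunConfig | None = None,
              stimulus_set: StimulusSet | None = None,
              neurons=None, truth: pd.DataFrame | None = None,
              features: FeatureTable | None = None,
              population_kwargs: dict | None = None) -> dict:
    """Generate (or reuse) a synthetic study and run the full pipeline."""
    cfg = (cfg or RunConfig()).validate()
    if stimulus_set is None:
        stimulus_set = generate_contours(
            StimulusSetConfig(seed=cfg.seed_stimuli))
    if neurons is None:
        neurons, truth = make_population(seed=cfg.seed_neurons,
                                         **(population_kwargs or {}))
    if features is None:
        features = feature_tables(stimulus_set,
                                  {n.neuron_id: n.crf for n in neurons},
                                  cfg)
    responses = simulate_responses(neurons, stimulus_set.stimuli, features,
                                   seed=cfg.seed_responses)
    geometry_of = stimulus_set.geometry_of()
    kinds = stimulus_set.kinds
    tuning_df = tuning_analysis(features, responses, geometry_of, cfg)
    mi = mi_analysis(features, responses, geometry_of, tuning_df, cfg)
    pop = population_analysis(responses, kinds, tuning_df, cfg)
    return {"stimulus_set": stimulus_set, "neurons": neurons,
            "truth": truth, "features": features, "responses": responses,
            "tuning": tuning_df, "mi": mi, "population": pop}
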