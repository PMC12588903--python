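"""End-to-end batch-safety evaluation: qualification → classification →
dose-response tiers → marker selection → combination analysis → chromaticity.

``run_pipeline`` executes every stage on either user-supplied CSV inputs or
the synthetic generators, writes one CSV/JSON artifact per stage into a run
directory, and finishes with a manifest recording the configuration, seed and
SHA-256 content hash of every artifact.  With a fixed seed and configuration
the whole run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics, chromaticity, combination, compounds, dose_response, markers, synthetic

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    out_dir: str | Path = "pmtox_run"
    seed: int = 0
    # inputs; None means "generate synthetically"
    compound_csv: str | None = None
    compound_metadata_csv: str | None = None
    ray_csv: str | None = None  # columns dose_t, dose_e, y_obs
    chromaticity_csv: str | None = None
    # analysis parameters
    scaling_mode: str = "unit_variance"
    hca_linkage: str = "ward"
    hca_metric: str = "euclidean"
    n_groups: int = 4
    n_orthogonal: int = 1
    n_permutations: int = 200
    vip_threshold: float = 1.0
    q_threshold: float = 0.05
    tier_high_cutoff: float = 390.0
    tier_low_cutoff: float = 450.0
    ci_decimals: int = 4
    pca_components: int = 2
    run_chromaticity: bool = True
    synthetic: synthetic.SyntheticConfig | None = None

    def __post_init__(self) -> None:
        if not self.tier_high_cutoff < self.tier_low_cutoff:
            raise ValueError("tier cutoffs must be ordered high < low")
        if self.n_permutations <= 0 or self.n_groups <= 0:
            raise ValueError("counts must be positive")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        syn = d.pop("synthetic")
        if syn is not None:
            syn["compound_means"] = self.synthetic.compound_means.to_dict()
            syn["hill_params_by_group"] = {
                g: dataclasses.asdict(h) for g, h in self.synthetic.hill_params_by_group.items()
            }
        d["synthetic"] = syn
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("compound_table")
def _load_table(cfg: PipelineConfig) -> compounds.CompoundTable:
    if cfg.compound_csv is not None:
        if cfg.compound_metadata_csv is None:
            raise ValueError("compound_metadata_csv required with compound_csv")
        return compounds.read_compound_table(cfg.compound_csv, cfg.compound_metadata_csv)
    syn = cfg.synthetic or synthetic.SyntheticConfig(seed=cfg.seed)
    return synthetic.generate_compound_table(syn)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = cfg.synthetic or synthetic.SyntheticConfig(seed=cfg.seed)
    artifacts: dict[str, Path] = {}
    notes: dict[str, str] = {}

    table = _load_table(cfg)
    table.write_csv(out / "compound_table.csv", out / "compound_metadata.csv")
    artifacts["compound_table"] = out / "compound_table.csv"
    artifacts["compound_metadata"] = out / "compound_metadata.csv"

    # --- qualification
    qual = compounds.qualify_batches(table)
    compounds.write_qualification_report(qual, out / "qualification.json")
    artifacts["qualification"] = out / "qualification.json"

    # --- chemometric classification
    try:
        scaled = chemometrics.autoscale(table.concentrations, cfg.scaling_mode)
        pca = chemometrics.fit_pca(scaled, cfg.pca_components)
        q2 = chemometrics.pca_q2(scaled, cfg.pca_components, seed=cfg.seed)
        labels, _ = chemometrics.hca(
            scaled.values, linkage=cfg.hca_linkage, metric=cfg.hca_metric, k=cfg.n_groups)
        cls = pd.DataFrame(
            {
                "batch": table.batch_ids,
                "cluster": labels,
                "group": [table.group.get(b, "") if table.group else "" for b in table.batch_ids],
                "pc1": pca.scores[:, 0],
                "pc2": pca.scores[:, 1] if pca.scores.shape[1] > 1 else np.nan,
            }
        )
        cls.to_csv(out / "classification.csv", index=False)
        (out / "pca_diagnostics.json").write_text(json.dumps(
            {
                "explained_variance_fraction": pca.explained_variance_fraction.tolist(),
                "r2x_cum": pca.r2x_cum,
                "q2_per_component": q2.tolist(),
            }, indent=2))
        artifacts["classification"] = out / "classification.csv"
        artifacts["pca_diagnostics"] = out / "pca_diagnostics.json"
    except Exception as exc:
        raise PipelineError(f"stage 'classification' failed: {exc}") from exc

    # --- dose-response tiers (synthetic plates per group)
    doses = np.array([1.0, 10.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 700.0, 1000.0])
    group_of = table.group or dict(zip(table.batch_ids, [str(l) for l in labels]))
    tier_rows = []
    curves: dict[str, dose_response.HillParams] = {}
    try:
        for i, g in enumerate(sorted(set(group_of.values()))):
            curve = syn.hill_params_by_group.get(g, dose_response.HillParams(0, 1, 450.0, 2.5))
            plate = synthetic.generate_viability_plate(
                curve, doses, syn.noise_sd_viability, seed=cfg.seed * 1000 + i)
            fit = dose_response.fit_hill(plate)
            curves[g] = fit.params
            tier_rows.append(
                {
                    "group": g,
                    "ic50_ug_ml": fit.params.ic50,
                    "slope": fit.params.slope,
                    "converged": fit.converged,
                    "extrapolated": fit.ic50_extrapolated,
                    "tier": dose_response.classify_toxicity_tier(
                        fit.params.ic50, cfg.tier_low_cutoff, cfg.tier_high_cutoff),
                }
            )
        tiers = pd.DataFrame(tier_rows)
        tiers.to_csv(out / "toxicity_tiers.csv", index=False)
        artifacts["toxicity_tiers"] = out / "toxicity_tiers.csv"
    except Exception as exc:
        raise PipelineError(f"stage 'dose_response' failed: {exc}") from exc

    # --- marker selection between least and most toxic groups
    try:
        # sub-limit groups (majority of batches unqualified) are excluded from
        # the toxicity comparison, mirroring the study design
        qualified_by_batch = {r.batch_id: r.qualified for r in qual}
        group_qualified = {
            g: np.mean([qualified_by_batch[b] for b in table.batch_ids
                        if group_of[b] == g]) >= 0.5
            for g in set(group_of.values())
        }
        eligible = tiers[tiers["group"].astype(str).map(group_qualified)]
        if len(eligible) < 2:
            eligible = tiers
        tiers_sorted = eligible.sort_values("ic50_ug_ml")
        g_toxic = str(tiers_sorted.iloc[0]["group"])
        g_safe = str(tiers_sorted.iloc[-1]["group"])
        sel = [b for b in table.batch_ids if group_of[b] in (g_safe, g_toxic)]
        sub = table.subset(sel)
        y = np.array([group_of[b] for b in sub.batch_ids])
        scaled2 = chemometrics.autoscale(sub.concentrations, cfg.scaling_mode)
        opls = chemometrics.fit_oplsda(scaled2, y, cfg.n_orthogonal)
        perm = chemometrics.permutation_test(
            scaled2, y, cfg.n_orthogonal, cfg.n_permutations, seed=cfg.seed)
        t_stats, p_vals = [], []
        for j in range(len(sub.compound_ids)):
            t, p = markers.welch_t_test(
                sub.concentrations[y == g_safe, j], sub.concentrations[y == g_toxic, j])
            t_stats.append(t)
            p_vals.append(p)
        q_vals = markers.benjamini_hochberg(p_vals)
        marker_results = markers.select_markers(
            sub.compound_ids, opls.vip, q_vals, t_stats, p_vals,
            cfg.vip_threshold, cfg.q_threshold)
        pd.DataFrame(
            [{"compound": m.compound_id, "class": sub.compound_class[m.compound_id],
              "vip": m.vip, "t": m.t_statistic, "p": m.p_value, "q": m.q_value,
              "marker": m.is_marker}
             for m in marker_results]
        ).to_csv(out / "markers.csv", index=False)
        (out / "oplsda_diagnostics.json").write_text(json.dumps(
            {
                "groups": [g_safe, g_toxic],
                "r2x": opls.r2x, "r2y": opls.r2y, "q2": opls.q2,
                "n_orthogonal": opls.n_orthogonal,
                "permutation_valid": perm.valid,
                "q2_intercept": perm.q2_intercept,
                "n_permutations": perm.n_permutations,
            }, indent=2))
        artifacts["markers"] = out / "markers.csv"
        artifacts["oplsda_diagnostics"] = out / "oplsda_diagnostics.json"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'markers' failed: {exc}") from exc

    # --- combination analysis
    try:
        if cfg.ray_csv is not None:
            df = pd.read_csv(cfg.ray_csv)
            curve_t = combination.effect_curve_from_viability(curves[g_toxic])
            curve_e = combination.effect_curve_from_viability(curves[g_safe])
            ray = combination.CombinationRay(
                dose_t=df["dose_t"].to_numpy(), dose_e=df["dose_e"].to_numpy(),
                observed_effect=df["y_obs"].to_numpy(),
                curve_t=curve_t, curve_e=curve_e)
        else:
            curve_t = dose_response.HillParams(0.0, 100.0, 417.0, 2.5)
            curve_e = dose_response.HillParams(0.0, 100.0, 12.7, 2.5)
            pairs = list(zip(
                (30, 120, 180, 250, 300, 350, 400, 450, 500, 550),
                (1.25, 2.5, 5, 7.5, 10, 12.5, 15, 17.5, 20, 22.5)))
            ray = synthetic.generate_combination_ray(
                curve_t, curve_e, pairs, interaction="potency_shift",
                potency_factor=1.5, noise_sd=syn.noise_sd_viability * 100,
                seed=cfg.seed + 7)
        combo = combination.analyze_ray(ray)
        combo.to_csv(out / "combination.csv", index=False)
        artifacts["combination"] = out / "combination.csv"
    except Exception as exc:
        raise PipelineError(f"stage 'combination' failed: {exc}") from exc

    # --- chromaticity
    if cfg.run_chromaticity:
        try:
            if cfg.chromaticity_csv is not None:
                records = chromaticity.records_from_frame(pd.read_csv(cfg.chromaticity_csv))
            else:
                records = synthetic.generate_chromaticity(syn)
            summaries = chromaticity.aggregate_batches(records)
            ic50_by_batch = {
                b: float(tiers.set_index("group").loc[group_of[b], "ic50_ug_ml"])
                for b in table.batch_ids
                if group_of.get(b) in set(tiers["group"].astype(str))
            }
            reg = chromaticity.color_toxicity_regression(summaries, ic50_by_batch)
            labels_c, _ = chromaticity.color_hca(summaries, k=min(3, len(summaries)))
            pd.DataFrame(
                [{"batch": s.batch_id, "norm_r": s.norm_r, "norm_g": s.norm_g,
                  "norm_b": s.norm_b, "e_ab": s.e_ab, "L": s.mean_l,
                  "cluster": int(l), "complete": s.complete}
                 for s, l in zip(summaries, labels_c)]
            ).to_csv(out / "chromaticity_summary.csv", index=False)
            reg.to_csv(out / "chromaticity_regression.csv", index=False)
            artifacts["chromaticity_summary"] = out / "chromaticity_summary.csv"
            artifacts["chromaticity_regression"] = out / "chromaticity_regression.csv"
        except Exception as exc:
            raise PipelineError(f"stage 'chromaticity' failed: {exc}") from exc
    else:
        notes["chromaticity"] = "skipped: no chromaticity input requested"

    manifest = {
        "config": cfg.to_jsonable(),
        "seed": cfg.seed,
        "artifacts": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in artifacts.items()},
        "notes": notes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
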