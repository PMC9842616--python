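"""End-to-end pipeline: simulate -> QC -> fit -> metrics -> report.

Everything is driven by a single YAML/dict config with blocks ``task``,
``norms``, ``simulate``, ``fit`` and ``analyze``; the master seed makes the
whole bundle reproducible, and a manifest (config echo, seed, package
versions, output hashes) is written alongside the results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort, io, metrics, models

log = logging.getLogger("riskconform")

DEFAULT_CONFIG: dict = {
    "task": {"repeats": 4},
    "norms": {"offset": 0.20, "clip": [0.05, 0.95]},
    "simulate": {
        "n_per_cell": 90,
        "domains": ["moral", "monetary"],
        "n_constant_responders": 0,
        "n_failed_comprehension": 0,
        "n_failed_attention": 0,
    },
    "fit": {"quad_nodes": 21, "phases": ["baseline", "own_d0", "own_d3"]},
    "analyze": {"n_draws": 2000},
    "seed": 0,
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Run the full chain deterministically from the config seed.

    Writes trials.csv, truth.csv, participants.csv, qc_report.json,
    influence.csv, entropy.json, awareness.json, fit_summary.csv and
    manifest.json under ``out_dir``; returns the result bundle as a dict.
    Any stage failure aborts with a stage-labeled error.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        sim = cfg["simulate"]
        trials, truth, participants = cohort.simulate_cohort(
            n_per_cell=sim["n_per_cell"],
            domains=tuple(sim["domains"]),
            n_constant_responders=sim["n_constant_responders"],
            n_failed_comprehension=sim["n_failed_comprehension"],
            n_failed_attention=sim["n_failed_attention"],
            repeats=cfg["task"]["repeats"],
            seed=cfg["seed"],
        )
        log.info("simulate: %d trials, %d participants", len(trials), len(participants))

        stage = "qc"
        comp = participants.set_index("participant_id")["comprehension_wrong"]
        att = participants.set_index("participant_id")["attention_pass"]
        retained, report = io.apply_exclusions(trials, comp, att)
        log.info("qc: retained %d of %d participants", report.n_retained, report.n_input)

        stage = "fit"
        fits = {}
        for domain in sim["domains"]:
            dom_trials = retained[retained["domain"] == domain]
            spec = models.ModelSpec(
                phases=tuple(cfg["fit"]["phases"]), quad_nodes=cfg["fit"]["quad_nodes"]
            )
            fits[domain] = models.fit_mixed_logit(dom_trials, spec)
            log.info(
                "fit[%s]: loglik=%.1f re_sd=%.3f", domain, fits[domain].loglik,
                fits[domain].re_sd,
            )

        stage = "metrics"
        n_draws = cfg["analyze"]["n_draws"]
        influence_rows = []
        for domain in sim["domains"]:
            for frame in ("gain", "loss"):
                for norm in ("risk_averse", "risk_seeking"):
                    cond = {"domain": domain, "frame": frame, "norm_type": norm}
                    for pair in [("own_d0", "baseline"), ("own_d3", "baseline")]:
                        est = metrics.influence_curve(
                            retained[retained["domain"] == domain],
                            pair,
                            condition={"frame": frame, "norm_type": norm},
                            fit=fits[domain],
                            n_draws=n_draws,
                            seed=cfg["seed"],
                        )
                        influence_rows.append(
                            {
                                **cond,
                                "phase_pair": f"{pair[0]}_vs_{pair[1]}",
                                "marginal_delta": est.marginal_delta,
                                "ci_low": est.ci_low,
                                "ci_high": est.ci_high,
                                "abs_magnitude": est.abs_magnitude,
                            }
                        )
        influence = pd.DataFrame(influence_rows)

        entropy = {}
        awareness = {}
        for domain in sim["domains"]:
            dom_trials = retained[retained["domain"] == domain]
            es = metrics.entropy_phase_comparison(dom_trials, "baseline", "own_d0")
            entropy[domain] = {
                "mean_entropy_baseline": float(es.per_participant["baseline"].mean()),
                "mean_entropy_own_d0": float(es.per_participant["own_d0"].mean()),
                "wilcoxon_statistic": es.statistic,
                "p_value": es.p_value,
                "n_pairs": es.n_pairs,
            }
            conf = metrics.participant_conformity(dom_trials)
            aware = participants.set_index("participant_id")["awareness"]
            corr = metrics.awareness_conformity_correlation(aware, conf)
            awareness[domain] = {"r": corr.r, "df": corr.df, "p": corr.p}

        stage = "report"
        io.write_trials(trials, out / "trials.csv")
        truth.to_csv(out / "truth.csv", index=False)
        participants.to_csv(out / "participants.csv", index=False)
        (out / "qc_report.json").write_text(json.dumps(report.summary(), indent=2))
        influence.to_csv(out / "influence.csv", index=False)
        (out / "entropy.json").write_text(json.dumps(entropy, indent=2))
        (out / "awareness.json").write_text(json.dumps(awareness, indent=2))
        fit_rows = []
        for domain, fit in fits.items():
            se = np.sqrt(np.diag(fit.vcov))
            for i, name in enumerate(fit.fixed_effects.index):
                fit_rows.append(
                    {
                        "domain": domain,
                        "term": name,
                        "estimate": fit.fixed_effects.iloc[i],
                        "se": se[i],
                    }
                )
            fit_rows.append(
                {"domain": domain, "term": "re_sd", "estimate": fit.re_sd, "se": np.nan}
            )
        pd.DataFrame(fit_rows).to_csv(out / "fit_summary.csv", index=False)

        manifest = {
            "package": "riskconform",
            "version": __version__,
            "seed": cfg["seed"],
            "config": cfg,
            "outputs": {
                p.name: _hash_file(p)
                for p in sorted(out.iterdir())
                if p.suffix in {".csv", ".json"} and p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "qc": report.summary(),
        "influence": influence,
        "entropy": entropy,
        "awareness": awareness,
        "manifest": manifest,
    }
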