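"""End-to-end two-tier screening pipeline.

Stage order mirrors the experimental workflow: monotherapy fits -> EC25
derivation -> single-dose pair screen with Bliss-excess statistics -> hit
selection -> 8x8 matrix scoring of the top hits with the four reference
models -> strict classification; independently, signature-reversal scoring
of DE tables.  ``run_pipeline`` executes it on synthetic data from a
seeded world and writes per-stage CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .doseresponse import HillFit, absolute_ic50, ec_f, fit_hill
from .io import write_json
from .primaryscreen import CombinationMeasurement, evaluate_pair, select_hits
from .reversal import score_reversal
from .simulate import SimulationSpec, gen_de_table, gen_monotherapy, gen_primary_screen, gen_surface
from .surface import score_surface

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "load_config", "run_pipeline", "evaluate_screen_table"]

DEFAULTS = {
    "seed": 0,
    "alpha": 0.05,
    "tau": 5.0,
    "padj_max": 0.05,
    "lfc_min": 2.0,
    "noise_sd": 0.02,
    "n_replicates": 4,
    "n_compounds": 6,
    "planted_excess": -0.2,
    "planted_delta": 0.10,
    "reversal_fraction": 0.5,
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path) -> dict:
    cfg = dict(DEFAULTS)
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise PipelineError("config", f"missing input path {p}")
        loaded = yaml.safe_load(p.read_text()) or {}
        cfg.update(loaded)
    return cfg


def evaluate_screen_table(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Score every pair in a long-format primary-screen table.

    Returns one row per pair: mean_excess, t, p, hit; sorted most
    synergistic first.
    """
    rows = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        a = grp["compound_a"].iloc[0]
        b = grp["compound_b"].iloc[0]
        arms = {
            arm: sub.sort_values("replicate")["viability"].to_numpy(float)
            for arm, sub in grp.groupby("arm")
        }
        m = CombinationMeasurement(
            pair=(a, b), va=tuple(arms["A"]), vb=tuple(arms["B"]),
            vab=tuple(arms["AB"]),
        )
        r = evaluate_pair(m, alpha=alpha)
        rows.append(
            {
                "pair_id": pair_id,
                "compound_a": a,
                "compound_b": b,
                "mean_excess": r.mean_excess,
                "t": r.t_stat,
                "p": r.p_value,
                "hit": r.is_hit,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["mean_excess", "pair_id"], kind="stable"
    )
    return out.reset_index(drop=True)


def _default_world(cfg: dict) -> SimulationSpec:
    """Deterministic per-compound Hill parameters for the synthetic run."""
    rng = np.random.default_rng(cfg["seed"])
    compounds = {}
    for i in range(cfg["n_compounds"]):
        name = f"CPD{i + 1:02d}"
        compounds[name] = HillFit(
            emax=float(rng.uniform(0.7, 1.0)),
            ec50_rel=float(10.0 ** rng.uniform(-1.0, 1.0)),
            hill_slope=float(rng.uniform(0.8, 2.0)),
        )
    return SimulationSpec(
        seed=cfg["seed"],
        noise_sd=cfg["noise_sd"],
        n_replicates=cfg["n_replicates"],
        compounds=compounds,
        planted_delta=cfg["planted_delta"],
        planted_block=(2, 2),
        reversal_fraction=cfg["reversal_fraction"],
    )


def run_pipeline(config=None, out_dir="synscreen_out") -> dict:
    """Run the full synthetic two-tier workflow and write a report bundle.

    Stages: simulate monotherapies and fit them; derive EC25 doses;
    simulate and score the primary pair screen (one planted synergist);
    score the top hit's 8x8 surface with all four models and classify;
    score a simulated DE table against its planted signature.  Returns the
    machine-readable summary (also written to ``summary.json``).
    """
    cfg = load_config(config) if not isinstance(config, dict) else {**DEFAULTS, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = _default_world(cfg)
    names = sorted(spec.compounds)

    # --- stage: monotherapy fits -------------------------------------
    fits, fit_rows = {}, []
    for k, name in enumerate(names):
        sub = dataclasses.replace(spec, seed=spec.seed + 1000 + k)
        reps = gen_monotherapy(sub, name)
        pts = [p for rep in reps for p in rep]
        try:
            f = fit_hill(pts, compound=name)
        except Exception as e:  # unfittable compound: excluded downstream
            logger.warning("fit failed for %s: %s", name, e)
            continue
        fits[name] = f
        fit_rows.append(
            {
                "compound": name, "emax": f.emax, "ec50_rel_uM": f.ec50_rel,
                "abs_ic50_uM": absolute_ic50(f), "hill_slope": f.hill_slope,
                "rss": f.rss, "n": f.n_points, "ec25_uM": ec_f(f, 25.0),
            }
        )
    if len(fits) < 2:
        raise PipelineError("fit", "fewer than two fittable compounds")
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)

    # --- stage: primary screen ---------------------------------------
    fitted = sorted(fits)
    planted_pair = (fitted[0], fitted[1])
    screen = gen_primary_screen(
        spec, compounds=fitted, planted_pairs={planted_pair: cfg["planted_excess"]}
    )
    screen.to_csv(out / "primary_screen.csv", index=False)
    results = evaluate_screen_table(screen, alpha=cfg["alpha"])
    results.to_csv(out / "primary_results.csv", index=False)
    hits = results[results["hit"]]
    summary_screen = {
        "n_pairs": int(len(results)),
        "n_hits": int(len(hits)),
        "hit_rate_percent": round(100.0 * len(hits) / len(results), 1),
    }

    # --- stage: matrix scoring of the top hit ------------------------
    if len(hits):
        top = hits.iloc[0]
        a, b = top["compound_a"], top["compound_b"]
    else:  # no hit: still demonstrate the secondary stage on the planted pair
        a, b = planted_pair
    surf = gen_surface(spec, a, b)
    scores = score_surface(surf, fits[a], fits[b], tau=cfg["tau"])
    synergy_report = {
        "pair": [a, b],
        "overall": {m: _r(v) for m, v in scores.overall.items()},
        "msa": {
            m: {"row": r.row, "col": r.col, "score": _r(r.mean_delta)}
            for m, r in scores.msa.items()
        },
        "css": _r(scores.css),
        "label": scores.label,
    }
    for model, d in scores.deltas.items():
        pd.DataFrame(d).to_csv(out / f"delta_{model}.csv", index=False)

    # --- stage: signature reversal -----------------------------------
    de, sig_df = gen_de_table(spec)
    de.to_csv(out / "de_table.tsv", sep="\t", index=False)
    sig_df.to_csv(out / "signature.tsv", sep="\t", index=False)
    from .reversal import SignatureGene

    sig = [SignatureGene(g, int(d)) for g, d in zip(sig_df["gene_id"], sig_df["direction"])]
    rev = score_reversal(
        de, sig, padj_max=cfg["padj_max"], lfc_min=cfg["lfc_min"],
        name=f"{a}+{b}",
    )
    reversal_report = {
        "n_signature": rev.n_signature,
        "n_detected": rev.n_detected,
        "n_reversed": rev.n_reversed,
        "n_reversed_up": rev.n_reversed_up,
        "n_reversed_down": rev.n_reversed_down,
        "fraction_reversed_percent": _r(100.0 * rev.fraction_reversed),
    }

    summary = {
        "version": __version__,
        "seed": cfg["seed"],
        "parameters": {
            k: cfg[k] for k in ("alpha", "tau", "padj_max", "lfc_min", "noise_sd")
        },
        "fits": {"n_compounds": len(fits)},
        "primary_screen": summary_screen,
        "top_pair_synergy": synergy_report,
        "reversal": reversal_report,
    }
    write_json(out / "summary.json", summary)
    return summary


def _r(x, nd=4):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), nd)
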