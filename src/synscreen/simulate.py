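"""Seeded synthetic data for every pipeline stage.

The generators emulate the experimental designs the analysis consumes —
20-point half-dilution monotherapy curves with replicate noise, 8x8
half-log combination matrices built on a chosen null model with an
optional planted 3x3 synergy block, EC25 single-dose pair screens with
quadruplicate arms, and DESeq2-style differential-expression tables
carrying a directional signature with a planted reversal fraction.

Noise is Gaussian on the inhibition-fraction scale and homoscedastic;
with ``noise_sd = 0`` every generator reproduces its ground truth
exactly, so each scorer can be closed against the planted value.
Identical :class:`SimulationSpec` inputs yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doseresponse import DoseResponsePoint, HillFit, hill, invert_effect
from .primaryscreen import enumerate_pairs
from .surface import DoseGrid, ResponseSurface, design_matrix

__all__ = [
    "SimulationSpec",
    "gen_monotherapy",
    "gen_surface",
    "gen_primary_screen",
    "gen_de_table",
    "default_doses",
]

#: Default monotherapy design: 20-point 1:2 serial dilutions from 10 µM.
DEFAULT_TOP_DOSE_UM = 10.0
DEFAULT_N_DOSES = 20


@dataclasses.dataclass(frozen=True)
class SimulationSpec:
    """Stated world for the generators.

    Defaults mirror the screening conditions the analysis was built for:
    quadruplicate technical replicates, plate noise of 2% inhibition,
    half-log surfaces with 3 replicates, and a 297-gene directional
    signature inside a genome-scale DE table.
    """

    seed: int = 0
    noise_sd: float = 0.02
    n_replicates: int = 4
    compounds: Mapping[str, HillFit] = dataclasses.field(default_factory=dict)
    # surface interaction
    interaction_model: str = "bliss"  # null model: bliss | hsa | loewe
    planted_delta: float = 0.0
    planted_block: tuple[int, int] | None = None  # top-left in off-axis 7x7
    surface_replicates: int = 3
    # DE / signature world
    n_genes: int = 20000
    signature_size: int = 297
    reversal_fraction: float = 0.5
    effect_lfc: float = 3.0
    detected_fraction: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.reversal_fraction <= 1:
            raise ValueError("reversal_fraction must be in [0, 1]")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size exceeds n_genes")
        if self.planted_block is not None:
            r, c = self.planted_block
            if not (0 <= r <= 4 and 0 <= c <= 4):
                raise ValueError(
                    "planted 3x3 block must lie within the off-axis 7x7 region "
                    f"(top-left in 0..4), got {self.planted_block}"
                )


def default_doses(
    top: float = DEFAULT_TOP_DOSE_UM, n: int = DEFAULT_N_DOSES
) -> np.ndarray:
    """1:2 serial dilutions from ``top`` µM, ``n`` points, high to low."""
    return top / 2.0 ** np.arange(n)


def _params(spec: SimulationSpec, compound: str) -> HillFit:
    try:
        return spec.compounds[compound]
    except KeyError:
        raise KeyError(f"unknown compound id {compound!r}") from None


def gen_monotherapy(
    spec: SimulationSpec, compound: str, doses: Sequence[float] | None = None
) -> list[list[DoseResponsePoint]]:
    """Replicate monotherapy curves: Hill(d) + N(0, noise_sd), clipped to
    [-0.2, 1.2].  Returns one list of points per replicate."""
    fit = _params(spec, compound)
    if doses is None:
        doses = default_doses()
    d = np.asarray(doses, float)
    if (d < 0).any():
        raise ValueError("doses must be non-negative")
    rng = np.random.default_rng(spec.seed)
    truth = hill(d, fit.emax, fit.ec50_rel, fit.hill_slope)
    reps = []
    for _ in range(spec.n_replicates):
        y = truth + rng.normal(0.0, spec.noise_sd, size=d.size) if spec.noise_sd else truth
        y = np.clip(y, -0.2, 1.2)
        reps.append([DoseResponsePoint(float(di), float(yi)) for di, yi in zip(d, y)])
    return reps


def _null_surface(grid: DoseGrid, fit_a: HillFit, fit_b: HillFit, model: str):
    da = np.asarray(grid.doses_a)
    db = np.asarray(grid.doses_b)
    ya = hill(da, fit_a.emax, fit_a.ec50_rel, fit_a.hill_slope)[:, None]
    yb = hill(db, fit_b.emax, fit_b.ec50_rel, fit_b.hill_slope)[None, :]
    if model == "bliss":
        return ya + yb - ya * yb
    if model == "hsa":
        return np.maximum(ya, yb)
    if model == "loewe":
        from scipy.optimize import brentq

        out = np.empty((da.size, db.size))
        y_max = min(fit_a.emax, fit_b.emax)
        for i, dai in enumerate(da):
            for j, dbj in enumerate(db):
                if dai == 0 and dbj == 0:
                    out[i, j] = 0.0
                    continue

                def g(y):
                    s = 0.0
                    if dai > 0:
                        s += dai / invert_effect(fit_a, y)
                    if dbj > 0:
                        s += dbj / invert_effect(fit_b, y)
                    return s - 1.0

                lo, hi = 1e-12, y_max - 1e-12
                if np.sign(g(lo)) == np.sign(g(hi)):
                    out[i, j] = y_max
                else:
                    out[i, j] = brentq(g, lo, hi, xtol=1e-12)
        return out
    raise ValueError(f"unknown interaction model {model!r}")


def gen_surface(
    spec: SimulationSpec, compound_a: str, compound_b: str
) -> ResponseSurface:
    """8x8 combination surface on the chosen null model of the true
    monotherapy curves, an optional planted delta inside a 3x3 off-axis
    block, plus replicate-averaged Gaussian noise."""
    fit_a = _params(spec, compound_a)
    fit_b = _params(spec, compound_b)
    grid = design_matrix(fit_a.ec50_rel, fit_b.ec50_rel)
    truth = _null_surface(grid, fit_a, fit_b, spec.interaction_model)
    if spec.planted_delta:
        if spec.planted_block is None:
            raise ValueError("planted_delta set but no planted_block given")
        r, c = spec.planted_block
        truth = truth.copy()
        truth[1 + r : 4 + r, 1 + c : 4 + c] += spec.planted_delta
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd:
        reps = truth[None, :, :] + rng.normal(
            0.0, spec.noise_sd, size=(spec.surface_replicates,) + truth.shape
        )
        mean = reps.mean(axis=0)
    else:
        mean = truth
    return ResponseSurface(grid=grid, inhibition=mean, n_reps=spec.surface_replicates)


def gen_primary_screen(
    spec: SimulationSpec,
    compounds: Sequence[str] | None = None,
    planted_pairs: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """EC25 single-dose pair screen as a long-format table.

    Each pair gets three arms (A, B, AB) of ``n_replicates`` viability
    fractions.  Single-agent true viability is 1 - 0.25*emax (the EC25 of
    the fitted span); non-planted pairs follow the multiplicative Bliss
    null exactly, planted pairs shift the combination arm by their (negative)
    excess.  Columns: pair_id, compound_a, compound_b, arm, replicate,
    viability.
    """
    if compounds is None:
        compounds = sorted(spec.compounds)
    planted = dict(planted_pairs or {})
    pairs = enumerate_pairs(list(compounds))
    bad = set(planted) - set(pairs)
    if bad:
        raise ValueError(f"planted pairs not in the enumerated screen: {sorted(bad)}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_replicates
    rows = []
    for a, b in pairs:
        va_true = 1.0 - 0.25 * _params(spec, a).emax
        vb_true = 1.0 - 0.25 * _params(spec, b).emax
        vab_true = va_true * vb_true + planted.get((a, b), 0.0)
        pair_id = f"{a}+{b}"
        for arm, truth in (("A", va_true), ("B", vb_true), ("AB", vab_true)):
            noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd else np.zeros(n)
            for r in range(n):
                rows.append(
                    {
                        "pair_id": pair_id,
                        "compound_a": a,
                        "compound_b": b,
                        "arm": arm,
                        "replicate": r + 1,
                        "viability": truth + noise[r],
                    }
                )
    return pd.DataFrame(rows)


def gen_de_table(spec: SimulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DESeq2-style DE table with a planted directional signature.

    Signature genes are assigned disease directions (+1/-1).  A
    ``detected_fraction`` of them draw padj below 0.05; of those, a
    ``reversal_fraction`` subset is reversed (log2fc = -direction x
    effect_lfc, jittered by noise_sd) and the rest change in the *same*
    direction, so the reversed share of detected genes equals the planted
    fraction exactly.  Undetected signature genes and background genes get
    null fold-changes and padj at or above 0.05.

    Returns ``(de_table, signature)``; the signature frame has columns
    gene_id, direction (+1/-1).
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"G{i:05d}" for i in range(1, spec.n_genes + 1)])
    sig_idx = rng.choice(spec.n_genes, size=spec.signature_size, replace=False)
    sig_idx.sort()
    directions = rng.choice([1, -1], size=spec.signature_size)

    n_detected = int(round(spec.detected_fraction * spec.signature_size))
    n_reversed = int(round(spec.reversal_fraction * n_detected))
    order = rng.permutation(spec.signature_size)
    detected_pos = order[:n_detected]
    reversed_pos = set(detected_pos[:n_reversed].tolist())
    detected_set = set(detected_pos.tolist())

    lfc = rng.normal(0.0, 0.3, size=spec.n_genes)
    padj = rng.uniform(0.05, 1.0, size=spec.n_genes)
    for k, (gi, dirn) in enumerate(zip(sig_idx, directions)):
        if k in detected_set:
            padj[gi] = rng.uniform(1e-8, 0.049)
            sign = -dirn if k in reversed_pos else dirn
            jitter = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
            lfc[gi] = sign * spec.effect_lfc + jitter
        else:
            padj[gi] = rng.uniform(0.05, 1.0)
            lfc[gi] = rng.normal(0.0, 0.3)

    de = pd.DataFrame({"gene_id": genes, "log2fc": lfc, "padj": padj})
    signature = pd.DataFrame(
        {"gene_id": genes[sig_idx], "direction": directions}
    )
    return de, signature
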