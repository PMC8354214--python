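"""Seeded multi-omic cohort simulator with known ground truth.

The generator emulates the data layout of a two-condition tumour study:
a small paired case/control discovery cohort plus a larger unpaired
evaluation cohort, with three expression tables (mRNA, miRNA, lncRNA),
a feature annotation, sample metadata with survival outcomes on the
evaluation cases, and a STRING-style PPI edge list.

Ground truth planted into the data:

* a subset of features in each class is differentially expressed (DE),
  shifted by +-de_log2fc on the log2 scale in case samples;
* n_hubs of the DE mRNAs are "hubs": each shares a latent factor with
  hub_partner_count DE miRNA/lncRNA partners so that the hub-partner
  correlation is approximately hub_corr, and each is wired into the PPI
  network with at least hub_ppi_degree edges (background genes draw
  about ppi_background_degree);
* a few hub mRNAs carry true proportional-hazards coefficients; the
  evaluation cases receive exponential event times with rate
  proportional to exp(coef . centered log2 expression) and independent
  censoring tuned to the requested censoring rate.

Expression is log-normal: Gaussian on the log2 scale, exponentiated, so
all values are strictly positive. The pipeline consumes normalized
intensities through Pearson correlations and log-scale contrasts, so
the Gaussian log-scale structure — not negative-binomial counts — is
the relevant one to emulate.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, FeatureAnnotation, PPINetwork, SampleTable

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticCohort", "simulate_cohort", "simulate_survival"]


@dataclass
class SimConfig:
    """Study-design knobs of the simulator.

    Defaults mirror a scaled-down tumour cohort: 150 mRNAs / 50 miRNAs /
    300 lncRNAs, 20 paired case/control discovery samples, a 120+15
    unpaired evaluation cohort, 10 hub mRNAs with 15 coexpression
    partners each at correlation 0.8 and PPI degree >= 10 against a
    background of about 2.
    """

    n_mrna: int = 150
    n_mirna: int = 50
    n_lncrna: int = 300
    n_case: int = 20
    n_control: int = 20
    n_case_eval: int = 120
    n_control_eval: int = 15
    n_de_mrna: int = 30
    n_de_mirna: int = 25
    n_de_lncrna: int = 125
    n_hubs: int = 10
    hub_partner_count: int = 15
    hub_corr: float = 0.8
    de_log2fc: float = 2.0
    noise_sd: float = 1.0
    ppi_background_degree: int = 2
    hub_ppi_degree: int = 10
    ppi_score_range: tuple[float, float] = (0.4, 0.95)
    survival_coefficients: tuple[float, ...] = (-0.8, 0.6, -0.7, 0.5)
    baseline_hazard_rate: float = np.log(2) / 600.0  # median ~600 days at lp = 0
    censoring_rate: float = 0.3
    up_fraction: float = 0.75  # share of DE features shifted upward in cases
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_mrna, self.n_mirna, self.n_lncrna, self.n_case, self.n_control) <= 0:
            raise ValueError("feature and sample counts must be positive")
        if self.n_hubs > self.n_de_mrna or self.n_de_mrna > self.n_mrna:
            raise ValueError("need n_hubs <= n_de_mrna <= n_mrna")
        if self.n_de_mirna > self.n_mirna or self.n_de_lncrna > self.n_lncrna:
            raise ValueError("DE counts cannot exceed class sizes")
        if self.n_hubs * self.hub_partner_count > self.n_de_mirna + self.n_de_lncrna:
            raise ValueError(
                "not enough DE miRNA/lncRNA features to give every hub "
                f"{self.hub_partner_count} distinct partners"
            )
        if not (0 < self.hub_corr < 1):
            raise ValueError("hub_corr must lie in (0, 1)")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if len(self.survival_coefficients) > self.n_hubs:
            raise ValueError("at most one survival coefficient per hub")
        if self.hub_ppi_degree > self.n_de_mrna - 1:
            raise ValueError("hub_ppi_degree cannot exceed n_de_mrna - 1")
        lo, hi = self.ppi_score_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("ppi_score_range must be within [0, 1]")


@dataclass
class SyntheticTruth:
    """What was planted: hubs, DE directions, survival effects."""

    hub_ids: list[str]
    de_direction: dict[str, str]  # feature_id -> "up"/"down" (cases vs controls)
    hub_partners: dict[str, list[str]]
    survival_ids: list[str]
    survival_coefficients: np.ndarray

    def de_ids_of(self, prefix: str) -> list[str]:
        return [f for f in self.de_direction if f.startswith(prefix)]


@dataclass
class SyntheticCohort:
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    lncrna: ExpressionMatrix
    annotation: FeatureAnnotation
    samples: SampleTable
    ppi: PPINetwork
    truth: SyntheticTruth


@dataclass
class _Structure:
    """Frozen feature-level parameters shared by every drawn sample."""

    ids: dict[str, list[str]]
    baselines: dict[str, np.ndarray]
    de_shift: dict[str, np.ndarray]  # signed log2 shift per feature, 0 if not DE
    hub_ids: list[str]
    partner_of: dict[str, str]  # partner feature id -> its hub


_PREFIX = {"mRNA": "mRNA_", "miRNA": "miR_", "lncRNA": "lnc_"}


def _plant_structure(cfg: SimConfig, rng: np.random.Generator) -> tuple[_Structure, SyntheticTruth, PPINetwork]:
    ids = {
        "mRNA": [f"mRNA_{i + 1:04d}" for i in range(cfg.n_mrna)],
        "miRNA": [f"miR_{i + 1:04d}" for i in range(cfg.n_mirna)],
        "lncRNA": [f"lnc_{i + 1:04d}" for i in range(cfg.n_lncrna)],
    }
    baselines = {
        cls: rng.uniform(4.0, 10.0, size=len(ids[cls])) for cls in ids
    }

    de_sets = {
        "mRNA": list(rng.choice(ids["mRNA"], size=cfg.n_de_mrna, replace=False)),
        "miRNA": list(rng.choice(ids["miRNA"], size=cfg.n_de_mirna, replace=False)),
        "lncRNA": list(rng.choice(ids["lncRNA"], size=cfg.n_de_lncrna, replace=False)),
    }
    hub_ids = de_sets["mRNA"][: cfg.n_hubs]

    # disjoint partner blocks drawn from the DE miRNA/lncRNA pool
    pool = de_sets["miRNA"] + de_sets["lncRNA"]
    pool = list(rng.permutation(pool))
    partner_of: dict[str, str] = {}
    hub_partners: dict[str, list[str]] = {}
    for i, hub in enumerate(hub_ids):
        block = pool[i * cfg.hub_partner_count : (i + 1) * cfg.hub_partner_count]
        hub_partners[hub] = block
        for p in block:
            partner_of[p] = hub

    # signed DE shifts; partners inherit their hub's direction so the
    # case-shift reinforces rather than cancels the latent-factor coupling
    direction: dict[str, str] = {}
    for cls in de_sets:
        for f in de_sets[cls]:
            direction[f] = "up" if rng.random() < cfg.up_fraction else "down"
    for hub, block in hub_partners.items():
        for p in block:
            direction[p] = direction[hub]

    de_shift = {}
    for cls in ids:
        shift = np.zeros(len(ids[cls]))
        for j, f in enumerate(ids[cls]):
            if f in direction:
                shift[j] = cfg.de_log2fc if direction[f] == "up" else -cfg.de_log2fc
        de_shift[cls] = shift

    ppi = _build_ppi(cfg, ids["mRNA"], de_sets["mRNA"], hub_ids, rng)

    survival_ids = hub_ids[: len(cfg.survival_coefficients)]
    truth = SyntheticTruth(
        hub_ids=hub_ids,
        de_direction=direction,
        hub_partners=hub_partners,
        survival_ids=survival_ids,
        survival_coefficients=np.asarray(cfg.survival_coefficients, dtype=float),
    )
    structure = _Structure(ids, baselines, de_shift, hub_ids, partner_of)
    return structure, truth, ppi


def _build_ppi(
    cfg: SimConfig,
    mrna_ids: list[str],
    de_mrna: list[str],
    hub_ids: list[str],
    rng: np.random.Generator,
) -> PPINetwork:
    """Sparse background graph plus dense hub wiring within the DE set."""
    lo, hi = cfg.ppi_score_range
    edges: dict[tuple[str, str], float] = {}

    def add(a: str, b: str) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        if key not in edges:
            edges[key] = float(rng.uniform(lo, hi))

    hub_set = set(hub_ids)
    de_nonself = {h: [g for g in de_mrna if g != h] for h in hub_ids}
    for hub in hub_ids:
        targets = rng.choice(de_nonself[hub], size=cfg.hub_ppi_degree, replace=False)
        for t in targets:
            add(hub, t)
    for g in mrna_ids:
        if g in hub_set:
            continue
        k = rng.poisson(cfg.ppi_background_degree / 2.0)  # each endpoint initiates half
        for t in rng.choice(mrna_ids, size=k, replace=False):
            add(g, t)
    return PPINetwork.from_edges((a, b, s) for (a, b), s in edges.items())


def _draw_class(
    cls: str,
    structure: _Structure,
    cfg: SimConfig,
    case_mask: np.ndarray,
    factors: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Log2 expression (features x samples) for one RNA class."""
    ids = structure.ids[cls]
    n_samples = case_mask.size
    log2 = (
        structure.baselines[cls][:, None]
        + structure.de_shift[cls][:, None] * case_mask[None, :]
    )
    loading = np.sqrt(cfg.hub_corr)
    resid = np.sqrt(1.0 - cfg.hub_corr)
    for j, f in enumerate(ids):
        hub = f if f in factors else structure.partner_of.get(f)
        if hub is not None and hub in factors:
            z = loading * factors[hub] + resid * rng.standard_normal(n_samples)
        else:
            z = rng.standard_normal(n_samples)
        log2[j] += cfg.noise_sd * z
    return log2


def _draw_samples(
    structure: _Structure,
    cfg: SimConfig,
    n_case: int,
    n_control: int,
    prefix: str,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], list[str], np.ndarray]:
    sample_ids = [f"{prefix}C{i + 1:03d}" for i in range(n_case)] + [
        f"{prefix}N{i + 1:03d}" for i in range(n_control)
    ]
    case_mask = np.array([1.0] * n_case + [0.0] * n_control)
    factors = {h: rng.standard_normal(len(sample_ids)) for h in structure.hub_ids}
    matrices = {
        cls: 2.0 ** _draw_class(cls, structure, cfg, case_mask, factors, rng)
        for cls in structure.ids
    }
    return matrices, sample_ids, case_mask


def simulate_survival(
    expr: ExpressionMatrix,
    coefficients: np.ndarray,
    baseline_rate: float,
    censoring_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Exponential event times driven by a linear predictor on log2 expression.

    The hazard of patient i is baseline_rate * exp(lp_i) with
    lp_i = coefficients . (log2 expression, centered across patients).
    Censoring times are uniform on [0, c] with c tuned by bisection so
    the realized censoring fraction approximates censoring_rate.
    Returns a frame (sample_id, os_days, os_event).
    """
    rng = np.random.default_rng(seed)
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.size != len(expr.feature_ids):
        raise ValueError("one coefficient per expression row required")
    x = np.log2(expr.values + 1.0)
    lp = coefficients @ (x - x.mean(axis=1, keepdims=True))
    rates = baseline_rate * np.exp(lp)
    times = rng.exponential(1.0 / rates)
    n = times.size
    if censoring_rate == 0:
        observed, events = times, np.ones(n, dtype=int)
    else:
        u = rng.uniform(size=n)
        lo, hi = 1e-6, float(times.max()) * 1e3

        def censored_frac(c: float) -> float:
            return float((c * u < times).mean())

        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if censored_frac(mid) > censoring_rate:
                lo = mid
            else:
                hi = mid
        cens = hi * u
        events = (times <= cens).astype(int)
        observed = np.minimum(times, cens)
    return pd.DataFrame(
        {"sample_id": expr.sample_ids, "os_days": observed, "os_event": events}
    )


def simulate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Generate the full synthetic study under a frozen planted structure.

    Discovery samples (paired, ``C###``/``N###``) and evaluation samples
    (unpaired, ``EC###``/``EN###``) are drawn from the same structure, so
    a model discovered on one cohort is meaningful on the other. The
    evaluation cases carry simulated survival outcomes.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    structure, truth, ppi = _plant_structure(cfg, rng)

    disc, disc_ids, disc_mask = _draw_samples(
        structure, cfg, cfg.n_case, cfg.n_control, "", rng
    )
    rows = {cls: disc[cls] for cls in disc}
    sample_ids = list(disc_ids)
    case_mask = disc_mask
    cohort_col = ["discovery"] * len(disc_ids)
    patient = [f"P{i + 1:03d}" for i in range(cfg.n_case)] + [
        f"P{i + 1:03d}" for i in range(cfg.n_control)
    ]

    if cfg.n_case_eval + cfg.n_control_eval > 0:
        ev, ev_ids, ev_mask = _draw_samples(
            structure, cfg, cfg.n_case_eval, cfg.n_control_eval, "E", rng
        )
        rows = {cls: np.hstack([rows[cls], ev[cls]]) for cls in rows}
        sample_ids += ev_ids
        case_mask = np.concatenate([case_mask, ev_mask])
        cohort_col += ["evaluation"] * len(ev_ids)
        patient += [f"EP{i + 1:03d}" for i in range(len(ev_ids))]

    matrices = {
        cls: ExpressionMatrix(structure.ids[cls], sample_ids, rows[cls])
        for cls in rows
    }

    annot_rows = [
        {"feature_id": f, "rna_class": cls, "symbol": f}
        for cls in ("mRNA", "miRNA", "lncRNA")
        for f in structure.ids[cls]
    ]
    annotation = FeatureAnnotation(pd.DataFrame(annot_rows))

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": np.where(case_mask > 0, "case", "control"),
            "patient_id": patient,
            "cohort": cohort_col,
            "os_days": np.nan,
            "os_event": np.nan,
        }
    )
    if cfg.n_case_eval > 0 and len(truth.survival_ids):
        eval_case_ids = [
            s
            for s, c, m in zip(sample_ids, cohort_col, case_mask)
            if c == "evaluation" and m > 0
        ]
        surv_rows = [matrices["mRNA"].feature_ids.index(f) for f in truth.survival_ids]
        cols = [matrices["mRNA"].sample_ids.index(s) for s in eval_case_ids]
        surv_expr = ExpressionMatrix(
            truth.survival_ids, eval_case_ids, matrices["mRNA"].values[np.ix_(surv_rows, cols)]
        )
        surv = simulate_survival(
            surv_expr,
            truth.survival_coefficients,
            cfg.baseline_hazard_rate,
            cfg.censoring_rate,
            seed=int(rng.integers(2**31)),
        )
        meta = meta.set_index("sample_id")
        meta.loc[surv["sample_id"], "os_days"] = surv["os_days"].to_numpy()
        meta.loc[surv["sample_id"], "os_event"] = surv["os_event"].to_numpy()
        meta = meta.reset_index()

    return SyntheticCohort(
        mrna=matrices["mRNA"],
        mirna=matrices["miRNA"],
        lncrna=matrices["lncRNA"],
        annotation=annotation,
        samples=SampleTable(meta),
        ppi=ppi,
        truth=truth,
    )
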