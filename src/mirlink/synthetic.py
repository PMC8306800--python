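"""Synthetic inputs with known planted structure.

The real inputs of the pipeline are license-restricted (the registry
cohort) or external accessions (the expression cohorts, cell panels and
dependency screens).  This module generates structurally faithful
substitutes: a registry with group-dependent exponential (optionally
Weibull) disease-specific survival and independent censoring, an
expression cohort with monotone planted expression-progression
relationships, a claims table with decoy records, lognormal drug-activity
panels with planted expression correlation, and dependency-score matrices
with designated essential genes.

Everything is a pure function of (config, seed): reruns are bit-identical.
Each simulator draws from its own RNG stream derived from the master seed,
so adding draws to one simulator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dependency import DependencyMatrix

DEFAULT_AGENTS = ("cisplatin", "carboplatin", "paclitaxel", "etoposide")

# stream ids keep simulators decoupled: (master seed, stream) seeds each RNG
_STREAMS = {
    "registry": 1,
    "cohort": 2,
    "claims": 3,
    "cell_panel": 4,
    "dependency": 5,
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for every simulator.

    Stage/grade marginals loosely follow the registry margins of a large
    lung squamous carcinoma population (mostly T1-T3, node-negative
    predominant, grade 2-3); survival is exponential with a log-linear
    hazard in the progression components.
    """

    seed: int = 0
    n_registry: int = 20000
    n_cohort: int = 200
    n_mirna: int = 100
    # miRNA name -> slope of mean expression per unit progression severity
    planted_mirna_effects: dict = field(default_factory=dict)
    baseline_hazard: float = 0.02  # disease-specific deaths per month at severity 0
    hazard_loadings: tuple = (0.3, 0.3, 0.3, 0.3)  # (beta_T, beta_N, beta_M, beta_G)
    censor_rate: float = 0.01  # censoring events per month
    other_cause_death_prob: float = 0.2
    treatment_probs: dict = field(
        default_factory=lambda: {
            "surgery": 0.55,
            "radiation": 0.35,
            "preop_radiation": 0.3,  # conditional on surgery & radiation
            "cisplatin": 0.15,
            "carboplatin": 0.20,
            "paclitaxel": 0.20,
            "etoposide": 0.10,
        }
    )
    noise_sd: float = 0.5
    t_probs: tuple = (0.35, 0.30, 0.20, 0.15)  # T = 1..4
    n_probs: tuple = (0.55, 0.25, 0.20)  # N = 0..2
    g_probs: tuple = (0.05, 0.42, 0.53)  # G = 1..3
    weibull_shape: float = 1.0  # 1.0 = exponential
    claims_distractor_rate: float = 0.3

    def __post_init__(self):
        if min(self.n_registry, self.n_cohort, self.n_mirna) <= 0:
            raise ConfigurationError("counts must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ConfigurationError("censor_rate must be non-negative")
        if not 0.0 <= self.other_cause_death_prob <= 1.0:
            raise ConfigurationError("other_cause_death_prob must be in [0,1]")
        for k, p in self.treatment_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"treatment prob {k}={p} outside [0,1]")
        bad = set(self.planted_mirna_effects) - set(self.mirna_names)
        if bad:
            raise ConfigurationError(f"planted effects for unknown miRNAs: {sorted(bad)}")
        for probs, k in ((self.t_probs, 4), (self.n_probs, 3), (self.g_probs, 3)):
            if len(probs) != k or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError("stage/grade probabilities must sum to 1")
        if self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape must be positive")

    @property
    def mirna_names(self) -> list[str]:
        return [f"mir-{i:03d}" for i in range(1, self.n_mirna + 1)]

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def _draw_stage_grade(config: SimulationConfig, rng, n: int):
    t = rng.choice(np.arange(1, 5), size=n, p=config.t_probs)
    nn = rng.choice(np.arange(0, 3), size=n, p=config.n_probs)
    m = np.zeros(n, dtype=int)
    g = rng.choice(np.arange(1, 4), size=n, p=config.g_probs)
    return t, nn, m, g


def severity_score(t, n, m, g):
    """Composite progression score (T-1) + N + M + (G-1)."""
    return (np.asarray(t) - 1) + np.asarray(n) + np.asarray(m) + (np.asarray(g) - 1)


def _simulate_survival(config: SimulationConfig, rng, t, n, m, g):
    bt, bn, bm, bg = config.hazard_loadings
    log_rr = bt * (t - 1) + bn * n + bm * m + bg * (g - 1)
    rate = config.baseline_hazard * np.exp(log_rr)
    shape = config.weibull_shape
    # shape=1 reduces to Exponential(rate); otherwise Weibull with the same scale
    death = rng.standard_exponential(t.size) ** (1.0 / shape) / rate
    if config.censor_rate > 0:
        censor = rng.exponential(1.0 / config.censor_rate, size=t.size)
    else:
        censor = np.full(t.size, np.inf)
    observed = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    return observed, event


def simulate_registry(config: SimulationConfig) -> pd.DataFrame:
    """Registry cohort: staged patients with disease-specific survival and treatment flags.

    ``event`` is the disease-specific event indicator: deaths relabeled as
    other-cause (probability ``other_cause_death_prob``) become censoring
    events; ``death_cause`` keeps the original label.
    """
    rng = _rng(config, "registry")
    n = config.n_registry
    t, nn, m, g = _draw_stage_grade(config, rng, n)
    time, event = _simulate_survival(config, rng, t, nn, m, g)

    cause = np.where(event == 1, "disease", "none").astype(object)
    other = (event == 1) & (rng.random(n) < config.other_cause_death_prob)
    cause[other] = "other"
    event = np.where(other, 0, event)

    tp = config.treatment_probs
    surgery = rng.random(n) < tp.get("surgery", 0.0)
    radiation = rng.random(n) < tp.get("radiation", 0.0)
    preop = surgery & radiation & (rng.random(n) < tp.get("preop_radiation", 0.0))
    agent_flags = {
        a: rng.random(n) < tp.get(a, 0.0) for a in DEFAULT_AGENTS
    }
    chemo = [
        frozenset(a for a in DEFAULT_AGENTS if agent_flags[a][i]) for i in range(n)
    ]
    return pd.DataFrame(
        {
            "patient_id": [f"R{i:06d}" for i in range(1, n + 1)],
            "time": time,
            "event": event,
            "death_cause": cause,
            "t_stage": t,
            "n_stage": nn,
            "m_stage": m,
            "grade": g,
            "surgery": surgery,
            "radiation": radiation,
            "preop_radiation": preop,
            "chemo_agents": chemo,
        }
    )


def simulate_expression_cohort(config: SimulationConfig):
    """Expression cohort: (sample x miRNA matrix, clinical table).

    Planted miRNA j has expression ~ Normal(effect_j * severity, noise_sd);
    null miRNAs are Normal(0, noise_sd).  Survival follows the same hazard
    model as the registry, so a negative planted effect means low expression
    in advanced disease, i.e. high expression is protective.
    """
    rng = _rng(config, "cohort")
    n = config.n_cohort
    t, nn, m, g = _draw_stage_grade(config, rng, n)
    time, event = _simulate_survival(config, rng, t, nn, m, g)
    sev = severity_score(t, nn, m, g)

    names = config.mirna_names
    expr = rng.normal(0.0, config.noise_sd, size=(n, len(names)))
    for j, name in enumerate(names):
        eff = config.planted_mirna_effects.get(name)
        if eff is not None:
            expr[:, j] += eff * sev

    samples = [f"C{i:04d}" for i in range(1, n + 1)]
    expr_df = pd.DataFrame(expr, index=samples, columns=names)
    clinical = pd.DataFrame(
        {
            "patient_id": samples,
            "time": time,
            "event": event,
            "t_stage": t,
            "n_stage": nn,
            "m_stage": m,
            "grade": g,
        }
    )
    return expr_df, clinical


def simulate_claims(config: SimulationConfig, registry: pd.DataFrame, code_map=None) -> pd.DataFrame:
    """Claims table consistent with the registry's chemo-agent flags.

    Every flagged (patient, agent) pair yields at least one claim carrying
    that agent's procedure code together with a lung-cancer diagnosis code.
    Decoy claims are injected at ``claims_distractor_rate`` per patient:
    agent procedure codes paired with a non-lung diagnosis, and unrelated
    procedure codes paired with a lung diagnosis.  Naive code matching that
    skips the diagnosis check therefore over-counts.
    """
    from .treatment import default_code_map

    if code_map is None:
        code_map = default_code_map()
    rng = _rng(config, "claims")
    rows = []
    lung_codes = sorted(code_map.lung_diagnosis_codes)
    nonlung_codes = ["250.00", "401.9", "715.90"]
    other_procs = ["99213", "85025", "71020"]

    for pid, agents in zip(registry["patient_id"], registry["chemo_agents"]):
        for agent in sorted(agents):
            codes = sorted(code_map.agent_codes[agent])
            for _ in range(1 + rng.poisson(0.5)):
                rows.append(
                    (pid, codes[rng.integers(len(codes))], lung_codes[rng.integers(len(lung_codes))])
                )
    if config.claims_distractor_rate > 0:
        n_decoys = rng.binomial(config.n_registry, config.claims_distractor_rate)
        pids = registry["patient_id"].to_numpy()
        all_agent_codes = sorted({c for s in code_map.agent_codes.values() for c in s})
        for _ in range(n_decoys):
            pid = pids[rng.integers(len(pids))]
            if rng.random() < 0.5:
                # agent code without a lung diagnosis: must NOT create a flag
                rows.append(
                    (pid, all_agent_codes[rng.integers(len(all_agent_codes))],
                     nonlung_codes[rng.integers(len(nonlung_codes))])
                )
            else:
                # lung diagnosis on an unrelated procedure
                rows.append(
                    (pid, other_procs[rng.integers(len(other_procs))],
                     lung_codes[rng.integers(len(lung_codes))])
                )
    return pd.DataFrame(rows, columns=["patient_id", "procedure_code", "diagnosis_code"])


NCI60_ENDPOINTS = ("GI50", "TGI", "LC50")


def simulate_cell_panel(
    config: SimulationConfig,
    n_lines: int = 60,
    planted_corr: float = 0.0,
    frac_out_of_bounds: float = 0.0,
    drug: str = "drugX",
):
    """Cell-line panel: (miRNA x line expression matrix, long drug-activity table).

    ln(IC50) is standard normal across lines.  Planted miRNAs (those with a
    nonzero effect in the config) get expression correlated with drug
    *sensitivity* (-ln IC50) at |planted_corr|, signed like their survival
    effect; null miRNAs are independent noise.  GI50/TGI/LC50 endpoints are
    noisy shifted copies of ln(IC50).  When ``frac_out_of_bounds`` > 0 the
    dose window [min_dose, max_dose] is set to interior quantiles so that
    fraction of lines falls outside it.
    """
    if not -1.0 <= planted_corr <= 1.0:
        raise ConfigurationError("planted_corr must be in [-1, 1]")
    rng = _rng(config, "cell_panel")
    lines = [f"LINE{i:03d}" for i in range(1, n_lines + 1)]
    ln_ic50 = rng.normal(size=n_lines)
    sens = -(ln_ic50 - ln_ic50.mean()) / ln_ic50.std()  # standardized sensitivity

    names = config.mirna_names
    expr = np.empty((len(names), n_lines))
    r = abs(planted_corr)
    for j, name in enumerate(names):
        eff = config.planted_mirna_effects.get(name)
        noise = rng.normal(size=n_lines)
        if eff is None or r == 0.0:
            expr[j] = noise
        else:
            sign = 1.0 if eff > 0 else -1.0
            expr[j] = sign * r * sens + np.sqrt(1.0 - r * r) * noise
    expr_df = pd.DataFrame(expr, index=names, columns=lines)

    if frac_out_of_bounds > 0:
        lo = float(np.quantile(ln_ic50, frac_out_of_bounds / 2))
        hi = float(np.quantile(ln_ic50, 1.0 - frac_out_of_bounds / 2))
        min_dose, max_dose = lo, hi
    else:
        min_dose = max_dose = np.nan

    rows = [(ln, drug, "ln_IC50", float(v), min_dose, max_dose) for ln, v in zip(lines, ln_ic50)]
    for k, ep in enumerate(NCI60_ENDPOINTS):
        vals = ln_ic50 + 0.5 * k + rng.normal(0.0, 0.3, size=n_lines)
        rows.extend((ln, drug, ep, float(v), np.nan, np.nan) for ln, v in zip(lines, vals))
    activity = pd.DataFrame(
        rows, columns=["cell_line", "drug", "endpoint", "value", "min_dose", "max_dose"]
    )
    return expr_df, activity


def simulate_dependency_screens(
    config: SimulationConfig,
    n_genes: int = 100,
    n_lines: int | tuple[int, int] = (78, 92),
    essential_genes: tuple[str, ...] = (),
    n_controls: int = 10,
):
    """Raw CRISPR-like and RNAi-like dependency matrices.

    Designated essential genes (and the essential control set) score
    Normal(-1, 0.1) in every line; everything else Normal(0, 0.1).  A
    per-line affine distortion is then applied so that the median-anchored
    normalization has real work to do.
    """
    rng = _rng(config, "dependency")
    n_crispr, n_rnai = (n_lines, n_lines) if isinstance(n_lines, int) else n_lines
    filler = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    filler = [gene for gene in filler if gene not in set(essential_genes)]
    genes = list(essential_genes) + filler[: max(0, n_genes - len(essential_genes))]
    ess_ctl = [f"ESS_CTL{i:02d}" for i in range(1, n_controls + 1)]
    noness_ctl = [f"NONESS_CTL{i:02d}" for i in range(1, n_controls + 1)]
    all_genes = genes + ess_ctl + noness_ctl
    essential_rows = set(essential_genes) | set(ess_ctl)

    def one_screen(nl: int, screen_type: str) -> DependencyMatrix:
        cols = [f"{screen_type.upper()}_LINE{i:03d}" for i in range(1, nl + 1)]
        mean = np.array([-1.0 if gn in essential_rows else 0.0 for gn in all_genes])
        scores = rng.normal(mean[:, None], 0.1, size=(len(all_genes), nl))
        slope = rng.uniform(0.8, 1.5, size=nl)
        intercept = rng.uniform(-0.3, 0.3, size=nl)
        raw = scores * slope[None, :] + intercept[None, :]
        return DependencyMatrix(
            scores=pd.DataFrame(raw, index=all_genes, columns=cols),
            screen_type=screen_type,
            essential_controls=frozenset(ess_ctl),
            nonessential_controls=frozenset(noness_ctl),
        )

    return one_screen(n_crispr, "crispr"), one_screen(n_rnai, "rnai")
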