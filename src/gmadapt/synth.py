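"""Synthetic study generator with configurable planted effects.

Produces every input the pipeline consumes — participant cohort with
pre/post body composition, whole-room calorimetry gas traces, DLW isotope
records, a species phylogeny and pre/post relative-abundance tables — with
known ground truth: responder labels, true RMR/TDEE, planted predictor
species, a responder dispersion contrast, and Gaussian-copula-coupled
correlations between Shannon diversity and metabolic adaptation.

The DLW generator forward-simulates the exact inverse of the energetics
module's two-point model, so the zero-noise round trip is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import diversity
from .energetics import (
    DEFAULT_DLW,
    DLWConstants,
    DLWRecord,
    WEIR_VCO2_COEF,
    WEIR_VO2_COEF,
    delta_to_mole_fraction,
    mole_fraction_to_delta,
    tbw_from_ffm,
)

DOSE_18O_G_PER_KG_TBW = 1.8
DOSE_2H_G_PER_KG_TBW = 0.12
APE_18O = 10.0
APE_2H = 99.9
BASELINE_DELTA_18O = -8.0  # per mil, typical urine background
BASELINE_DELTA_2H = -50.0

# reference steady-state gas exchange: Weir(0.25, 0.20) * 1440 = 1720.8
_REF_VO2, _REF_VCO2, _REF_RMR = 0.25, 0.20, 1720.8

# abundance-model calibration (not paper claims; see module docs)
_MU_SD = 2.0  # spread of species log-abundance means
_SUBJECT_SD_RANGE = (0.40, 1.25)  # per-species subject-offset sd (dispersion driver)
_PRED_SUBJECT_SD = 0.25  # planted predictors are inter-individually stable
_SAMPLE_EPS_SD = 0.05  # residual per-sample log-abundance noise
_C_SHANNON0 = 0.12  # baseline evenness-latent gain
_C_SHANNON_DELTA = 0.10  # pre-to-post evenness-latent gain
_PRED_STRATUM = (0.55, 0.72)  # mu-percentile band predictors are drawn from


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study; all planted effects are explicit."""

    n_subjects: int = 16
    responder_fraction: float = 0.5
    n_species: int = 300
    n_predictor_species: int = 9
    predictor_log2_effect: float = 1.5
    responder_dispersion_scale: float = 0.5
    rho_shannon_tdee: float = 0.73
    rho_shannon0_rmr: float = -0.65
    tdee_true_range: tuple[float, float] = (2200.0, 3200.0)
    rmr_true_range: tuple[float, float] = (1400.0, 1900.0)
    trace_noise_sd: float = 0.02
    dlw_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_species < 2:
            raise ValueError("counts must be >= 2")
        if not (0.0 < self.responder_fraction < 1.0):
            raise ValueError("responder_fraction must lie in (0, 1)")
        if not (abs(self.rho_shannon_tdee) < 1 and abs(self.rho_shannon0_rmr) < 1):
            raise ValueError("|rho| must be < 1")
        if not (0 <= self.n_predictor_species < self.n_species):
            raise ValueError("n_predictor_species must be < n_species")
        n_resp = round(self.n_subjects * self.responder_fraction)
        if n_resp < 2 or self.n_subjects - n_resp < 2:
            raise ValueError(
                "responder_fraction leaves a group with < 2 subjects; "
                "rank tests need >= 2 per group"
            )


@dataclass
class GroundTruth:
    """Planted quantities that downstream stages should recover."""

    responder: np.ndarray
    rmr_true_pre: np.ndarray
    rmr_true_post: np.ndarray
    tdee_true_pre: np.ndarray
    tdee_true_post: np.ndarray
    adaptation_rmr_true: np.ndarray
    adaptation_tdee_true: np.ndarray
    predictor_species: list[str] = field(default_factory=list)
    realized_rho_shannon_tdee: float = float("nan")
    realized_rho_shannon0_rmr: float = float("nan")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        return {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d.items()
        }


# ---------------------------------------------------------------------------
# Cohort


def generate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Cohort table with planted responder labels and true energy values.

    Exactly round(n * responder_fraction) subjects get a strictly positive
    body-composition score (dFFM - dFM); weight change is centred at zero.
    True RMR/TDEE are affine in (FFM, FM) around the configured ranges
    plus a per-subject planted adaptation added to the post value.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_resp = round(n * config.responder_fraction)

    subject_id = np.array([f"S{i + 1:02d}" for i in range(n)])
    sex = np.array(["F"] * (n // 2) + ["M"] * (n - n // 2))
    rng.shuffle(sex)
    age = rng.integers(21, 46, n)
    height = np.where(
        sex == "F", rng.normal(1.63, 0.05, n), rng.normal(1.77, 0.06, n)
    )
    bmi_pre = rng.uniform(25.0, 30.0, n)
    weight_pre = bmi_pre * height**2
    fm_frac = np.where(
        sex == "F", rng.uniform(0.32, 0.42, n), rng.uniform(0.24, 0.34, n)
    )
    fm_pre = fm_frac * weight_pre
    ffm_pre = weight_pre - fm_pre

    responder = np.zeros(n, dtype=bool)
    responder[rng.permutation(n)[:n_resp]] = True
    score_mag = np.abs(rng.normal(0.0, 1.2, n)) + 0.15
    score = np.where(responder, score_mag, -score_mag)
    delta_weight = rng.normal(0.0, 1.5, n)
    delta_ffm = (delta_weight + score) / 2.0
    delta_fm = (delta_weight - score) / 2.0
    ffm_post = ffm_pre + delta_ffm
    fm_post = fm_pre + delta_fm
    weight_post = ffm_post + fm_post
    bmi_post = weight_post / height**2

    # true energies: affine in body composition around the configured ranges
    raw = 21.6 * ffm_pre + 3.1 * fm_pre
    rmr_mid = 0.5 * sum(config.rmr_true_range)
    tdee_mid = 0.5 * sum(config.tdee_true_range)
    rmr_pre = rmr_mid + (raw - raw.mean()) + rng.normal(0, 35, n)
    tdee_pre = tdee_mid + 1.6 * (raw - raw.mean()) + rng.normal(0, 80, n)
    adaptation_rmr = rng.normal(-60.0, 90.0, n)
    adaptation_tdee = rng.normal(120.0, 200.0, n)
    rmr_post = rmr_pre + 21.6 * delta_ffm + 3.1 * delta_fm + adaptation_rmr
    tdee_post = tdee_pre + 1.6 * (21.6 * delta_ffm + 3.1 * delta_fm) + adaptation_tdee

    vo2max_pre = rng.uniform(25.0, 40.0, n)
    vo2max_post = vo2max_pre + np.where(
        responder, rng.uniform(1.0, 4.0, n), rng.normal(0.0, 1.0, n)
    )
    kcal_in = rng.uniform(1900.0, 2700.0, n)

    cohort = pd.DataFrame(
        {
            "subject_id": subject_id,
            "sex": sex,
            "age": age,
            "height_m": height,
            "weight_pre": weight_pre,
            "weight_post": weight_post,
            "bmi_pre": bmi_pre,
            "bmi_post": bmi_post,
            "fm_pre": fm_pre,
            "fm_post": fm_post,
            "ffm_pre": ffm_pre,
            "ffm_post": ffm_post,
            "vo2max_pre": vo2max_pre,
            "vo2max_post": vo2max_post,
            "caloric_intake_pre": kcal_in,
            "caloric_intake_post": kcal_in + rng.normal(0.0, 60.0, n),
        }
    )
    truth = GroundTruth(
        responder=responder,
        rmr_true_pre=rmr_pre,
        rmr_true_post=rmr_post,
        tdee_true_pre=tdee_pre,
        tdee_true_post=tdee_post,
        adaptation_rmr_true=adaptation_rmr,
        adaptation_tdee_true=adaptation_tdee,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Gas-exchange traces


def generate_gas_trace(
    rmr_true: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    settle_amplitude: float = 0.0,
    settle_tau: float = 10.0,
) -> pd.DataFrame:
    """60-minute VO2/VCO2 trace whose final-20-minute Weir average is
    ``rmr_true`` (up to multiplicative noise of relative sd ``noise_sd``).

    A settling artifact (exponential decay, default 10-minute time
    constant) may be superimposed on minutes 0-39 only, so the
    final-window rule stays exact.
    """
    if rmr_true <= 0:
        raise ValueError("rmr_true must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    minutes = np.arange(60)
    scale = rmr_true / _REF_RMR
    vo2 = np.full(60, _REF_VO2 * scale)
    vco2 = np.full(60, _REF_VCO2 * scale)
    if settle_amplitude:
        settle = np.where(
            minutes < 40, 1.0 + settle_amplitude * np.exp(-minutes / settle_tau), 1.0
        )
        vo2 = vo2 * settle
        vco2 = vco2 * settle
    if noise_sd:
        vo2 = vo2 * (1.0 + noise_sd * rng.standard_normal(60))
        vco2 = vco2 * (1.0 + noise_sd * rng.standard_normal(60))
    return pd.DataFrame(
        {"minute": minutes, "vo2_L": np.abs(vo2), "vco2_L": np.abs(vco2)}
    )


# ---------------------------------------------------------------------------
# DLW records


def generate_dlw_record(
    tdee_true: float,
    tbw_true: float,
    rq: float = DEFAULT_DLW.rq,
    body_mass: float = 80.0,
    seed: int | None = None,
    noise_sd: float = 0.0,
    k_d: float = 0.09,
    elapsed_days: float = 10.0,
    constants: DLWConstants = DEFAULT_DLW,
) -> DLWRecord:
    """Forward-simulate a DLW record whose inversion recovers ``tdee_true``.

    Doses follow the 1.8 / 0.12 g per kg TBW rule; plateau and day-10
    enrichments come from the exact inverse of the two-point equation, so
    at ``noise_sd=0`` the energetics chain reproduces TDEE and TBW to
    machine precision.  ``noise_sd`` applies multiplicative analytic noise
    to the enrichment excesses.
    """
    if tdee_true <= 0 or tbw_true <= 0:
        raise ValueError("tdee_true and tbw_true must be positive")
    if not (0.7 <= rq <= 1.0):
        raise ValueError("respiratory quotient outside [0.7, 1.0]")
    rng = np.random.default_rng(seed)
    m = constants.molar_mass_water
    tbw_mol = tbw_true * 1000.0 / m
    n_o = constants.exchange_18o * tbw_mol
    n_d = constants.exchange_2h * tbw_mol

    dose_18o = DOSE_18O_G_PER_KG_TBW * tbw_true
    dose_2h = DOSE_2H_G_PER_KG_TBW * tbw_true
    plateau_o = dose_18o / m * APE_18O / 100.0 / n_o
    plateau_d = dose_2h / m * APE_2H / 100.0 / n_d

    rco2_l = tdee_true / (WEIR_VO2_COEF / rq + WEIR_VCO2_COEF)
    rco2_mol = rco2_l / constants.co2_litres_per_mol
    k_o = (rco2_mol / (constants.co2_coef * tbw_mol) + constants.kd_weight * k_d) / (
        constants.ko_weight
    )
    final_o = plateau_o * np.exp(-k_o * elapsed_days)
    final_d = plateau_d * np.exp(-k_d * elapsed_days)

    def _noisy(x: float) -> float:
        return float(x * (1.0 + noise_sd * rng.standard_normal())) if noise_sd else x

    xb_o = delta_to_mole_fraction(BASELINE_DELTA_18O, constants.r_std_18o)
    xb_d = delta_to_mole_fraction(BASELINE_DELTA_2H, constants.r_std_2h)

    def _delta(base, excess, r_std):
        return float(mole_fraction_to_delta(base + excess, r_std))

    return DLWRecord(
        dose_18o_g=dose_18o,
        dose_2h_g=dose_2h,
        ape_18o=APE_18O,
        ape_2h=APE_2H,
        baseline_18o=BASELINE_DELTA_18O,
        plateau4_18o=_delta(xb_o, _noisy(plateau_o), constants.r_std_18o),
        plateau5_18o=_delta(xb_o, _noisy(plateau_o), constants.r_std_18o),
        final2_18o=_delta(xb_o, _noisy(final_o), constants.r_std_18o),
        final3_18o=_delta(xb_o, _noisy(final_o), constants.r_std_18o),
        baseline_2h=BASELINE_DELTA_2H,
        plateau4_2h=_delta(xb_d, _noisy(plateau_d), constants.r_std_2h),
        plateau5_2h=_delta(xb_d, _noisy(plateau_d), constants.r_std_2h),
        final2_2h=_delta(xb_d, _noisy(final_d), constants.r_std_2h),
        final3_2h=_delta(xb_d, _noisy(final_d), constants.r_std_2h),
        elapsed_days=elapsed_days,
        body_mass_kg=body_mass,
    )


# ---------------------------------------------------------------------------
# Phylogeny


def generate_tree(species_ids: list[str] | int, seed: int | None = None) -> TreeNode:
    """Random rooted bifurcating tree with exponential branch lengths.

    Leaves are named by ``species_ids`` (or ``sp0000..`` when an int is
    given).  The root carries no branch length, so an n-leaf tree has
    2n - 2 edges (a 2-leaf tree is a single cherry with 2 edges).
    """
    if isinstance(species_ids, int):
        species_ids = species_universe(species_ids)
    if len(species_ids) < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    nodes = [
        TreeNode(name=s, length=float(rng.exponential(0.1)) + 1e-6)
        for s in species_ids
    ]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(i), int(j)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(
            children=[a, b], length=float(rng.exponential(0.1)) + 1e-6
        )
        nodes = [nd for t, nd in enumerate(nodes) if t not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def species_universe(n_species: int) -> list[str]:
    return [f"sp{i:04d}" for i in range(n_species)]


# ---------------------------------------------------------------------------
# Abundance tables


def generate_abundance(
    config: SynthConfig,
    cohort: pd.DataFrame,
    tree: TreeNode,
    truth: GroundTruth,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Pre/post logistic-normal compositions with the planted effects.

    Predictor species are shifted by ``predictor_log2_effect`` (log2) in
    responders; responder subject offsets are scaled by
    ``responder_dispersion_scale``; baseline Shannon and its pre-to-post
    change are coupled to the planted RMR/TDEE adaptations through
    Gaussian-copula latents driving per-subject evenness multipliers.
    Returns (samples x species table, sample metadata, updated truth).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    species = sorted(t.name for t in tree.tips())
    s = len(species)
    n = len(cohort)
    responder = truth.responder

    mu = rng.normal(0.0, _MU_SD, s)
    # predictors come from a mid-abundance stratum: abundant enough to pass
    # the downstream prevalence/abundance filter, but with |mu| small enough
    # that the subject-level evenness multiplier does not drown the shift
    order = np.argsort(mu)
    lo = int(_PRED_STRATUM[0] * s)
    hi = max(int(_PRED_STRATUM[1] * s), lo + config.n_predictor_species)
    stratum = order[lo:hi]
    pred_idx = rng.choice(stratum, size=config.n_predictor_species, replace=False)
    predictor_species = [species[i] for i in sorted(pred_idx)]

    tau = rng.uniform(*_SUBJECT_SD_RANGE, s)
    tau[pred_idx] = _PRED_SUBJECT_SD
    z = rng.normal(0.0, 1.0, (n, s)) * tau[None, :]
    z[responder] *= config.responder_dispersion_scale

    def _standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    def _coupled(target: np.ndarray, rho: float) -> np.ndarray:
        # latent with exact in-sample correlation rho against `target`
        # (copula noise orthogonalised against the target)
        t = _standardize(target)
        xi = rng.standard_normal(n)
        xi = _standardize(xi - (xi @ t) / (t @ t) * t)
        return rho * t + np.sqrt(1.0 - rho**2) * xi

    s0 = _coupled(truth.adaptation_rmr_true, config.rho_shannon0_rmr)
    d1 = _coupled(truth.adaptation_tdee_true, config.rho_shannon_tdee)
    beta0 = np.exp(-_C_SHANNON0 * s0)
    beta1 = np.exp(-_C_SHANNON_DELTA * d1)

    shift = np.zeros((n, s))
    shift[np.ix_(responder, pred_idx)] = config.predictor_log2_effect * np.log(2.0)

    base = mu[None, :] + z
    logits_pre = beta0[:, None] * base + shift + rng.normal(0, _SAMPLE_EPS_SD, (n, s))
    logits_post = (beta0 * beta1)[:, None] * base + shift + rng.normal(
        0, _SAMPLE_EPS_SD, (n, s)
    )

    def _softmax(l: np.ndarray) -> np.ndarray:
        e = np.exp(l - l.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    comp_pre = _softmax(logits_pre)
    comp_post = _softmax(logits_post)
    if comp_pre.max() > 0.99 or comp_post.max() > 0.99:
        raise ValueError(
            "planted effect degenerates the composition (a species exceeds "
            "0.99 relative abundance); reduce predictor_log2_effect"
        )

    ids = cohort["subject_id"].to_numpy()
    rows = np.vstack([comp_pre, comp_post])
    sample_ids = [f"{sid}_pre" for sid in ids] + [f"{sid}_post" for sid in ids]
    table = pd.DataFrame(rows, index=sample_ids, columns=species)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": np.concatenate([ids, ids]),
            "timepoint": ["pre"] * n + ["post"] * n,
            "responder": np.concatenate([responder, responder]),
        }
    ).set_index("sample_id")

    shannon_pre = np.array([diversity.shannon(r) for r in comp_pre])
    shannon_post = np.array([diversity.shannon(r) for r in comp_post])
    truth.predictor_species = predictor_species
    truth.realized_rho_shannon0_rmr = float(
        np.corrcoef(shannon_pre, truth.adaptation_rmr_true)[0, 1]
    )
    truth.realized_rho_shannon_tdee = float(
        np.corrcoef(shannon_post - shannon_pre, truth.adaptation_tdee_true)[0, 1]
    )
    return table, meta, truth


# ---------------------------------------------------------------------------
# Whole-study bundle


@dataclass
class SimulatedStudy:
    config: SynthConfig
    cohort: pd.DataFrame
    truth: GroundTruth
    tree: TreeNode
    abundance: pd.DataFrame
    sample_meta: pd.DataFrame
    gas_traces: dict[str, pd.DataFrame]  # key "S01_pre"
    dlw_records: dict[str, DLWRecord]


def simulate_study(config: SynthConfig) -> SimulatedStudy:
    """Generate the complete set of study inputs for one seed."""
    config.validate()
    cohort, truth = generate_cohort(config)
    master = np.random.default_rng(config.seed)
    seeds = iter(master.integers(0, 2**31 - 1, size=4 + 4 * len(cohort)))
    tree = generate_tree(species_universe(config.n_species), int(next(seeds)))
    abundance, meta, truth = generate_abundance(
        config, cohort, tree, truth, int(next(seeds))
    )
    gas_traces: dict[str, pd.DataFrame] = {}
    dlw_records: dict[str, DLWRecord] = {}
    for i, row in cohort.iterrows():
        for tp, rmr, tdee in (
            ("pre", truth.rmr_true_pre[i], truth.tdee_true_pre[i]),
            ("post", truth.rmr_true_post[i], truth.tdee_true_post[i]),
        ):
            key = f"{row.subject_id}_{tp}"
            gas_traces[key] = generate_gas_trace(
                rmr, config.trace_noise_sd, int(next(seeds)),
                settle_amplitude=0.3,
            )
            dlw_records[key] = generate_dlw_record(
                tdee,
                tbw_from_ffm(row[f"ffm_{tp}"]),
                body_mass=row[f"weight_{tp}"],
                seed=int(next(seeds)),
                noise_sd=config.dlw_noise_sd,
            )
    return SimulatedStudy(
        config=config, cohort=cohort, truth=truth, tree=tree,
        abundance=abundance, sample_meta=meta,
        gas_traces=gas_traces, dlw_records=dlw_records,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict:
    """Write all study inputs as plain-text files plus a run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.cohort.to_csv(out / "participants.csv", index=False)

    traces_dir = out / "traces"
    traces_dir.mkdir(exist_ok=True)
    for key, trace in study.gas_traces.items():
        trace.to_csv(traces_dir / f"{key}.csv", index=False)

    dlw_rows = []
    for key, rec in study.dlw_records.items():
        sid, tp = key.rsplit("_", 1)
        dlw_rows.append({"subject_id": sid, "timepoint": tp, **asdict(rec)})
    pd.DataFrame(dlw_rows).to_csv(out / "dlw.csv", index=False)

    table_out = study.abundance.T
    table_out.index.name = "species_id"
    table_out.to_csv(out / "abundance.tsv", sep="\t")
    study.sample_meta.to_csv(out / "sample_meta.csv")

    with open(out / "tree.nwk", "w") as fh:
        study.tree.write(fh)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(study.truth.to_json_dict(), fh, indent=2)
    manifest = {
        "seed": study.config.seed,
        "config": asdict(study.config),
        "files": [
            "participants.csv", "traces/", "dlw.csv", "abundance.tsv",
            "sample_meta.csv", "tree.nwk", "ground_truth.json",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
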