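"""Synthetic sorted and bulk methylome cohorts with full ground truth.

The generator emulates the statistical structure of a sorted neuron/glia
brain-methylation study on a 450k-style array:

* ~12% of probes differ between the two cell fractions by at least 0.20
  beta (a bit more than half hypermethylated in neurons);
* small disjoint probe subsets carry cell-type-specific linear age slopes
  (some with opposing signs in the two fractions) and Braak-stage effects;
* sex and array-batch offsets;
* Braak stage is assigned from a latent score correlated with age, so age
  and pathology are confounded as in real autopsy cohorts;
* bulk samples are proportion-weighted mixtures of the two cell-type
  means, with the neuronal weight drifting with age and Braak stage.

Observed beta values are drawn from a beta distribution parameterised by
mean ``m`` and concentration ``phi`` (``Beta(m*phi, (1-m)*phi)``), keeping
all values inside (0, 1).  Effects act additively on the beta scale with
age centred at ``age_center``, so the per-probe baselines ``mu_*`` are the
means at the cohort centre and planted cell-type differences are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import AUTOSOMES, validate_sample_sheet

#: threshold defining a planted cell-type difference (delta beta)
CT_DELTA = 0.20

#: approximate 450k array design proportions over region classes
REGION_DESIGN_PROPS = {
    "TSS1500": 0.13,
    "TSS200": 0.10,
    "5UTR": 0.12,
    "1stExon": 0.07,
    "Body": 0.31,
    "3UTR": 0.03,
    "intergenic": 0.24,
}


@dataclass
class SyntheticDesign:
    """Per-probe generative parameters plus cohort-level sampling rules."""

    probe_ids: np.ndarray
    mu_neuron: np.ndarray
    mu_glia: np.ndarray
    age_slope_neuron: np.ndarray
    age_slope_glia: np.ndarray
    braak_effect_neuron: np.ndarray
    braak_effect_glia: np.ndarray
    sex_effect: np.ndarray
    batch_effects: dict = field(default_factory=dict)
    phi: float = 200.0
    age_low: float = 30.0
    age_high: float = 95.0
    age_center: float = 62.5
    braak_age_corr: float = 0.5
    braak_probs: tuple = (0.20, 0.15, 0.15, 0.12, 0.10, 0.14, 0.14)
    w0: float = 0.55
    w_age: float = -0.002
    w_braak: float = -0.01
    w_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        n = len(self.probe_ids)
        for name in (
            "mu_neuron", "mu_glia", "age_slope_neuron", "age_slope_glia",
            "braak_effect_neuron", "braak_effect_glia", "sex_effect",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ConfigError(f"design field {name} must have shape ({n},)")
            setattr(self, name, arr)
        if self.phi <= 0:
            raise ConfigError("phi must be positive")
        if abs(np.round(sum(self.braak_probs), 9) - 1.0) > 1e-9:
            raise ConfigError("braak_probs must sum to 1")
        if np.any((self.mu_neuron < 0.01) | (self.mu_neuron > 0.99)) or np.any(
            (self.mu_glia < 0.01) | (self.mu_glia > 0.99)
        ):
            raise ConfigError("baseline means must lie in [0.01, 0.99]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def is_ct(self) -> np.ndarray:
        """Planted cell-type-different probes (|mu_n - mu_g| >= 0.20)."""
        return np.abs(self.mu_neuron - self.mu_glia) >= CT_DELTA - 1e-12

    def truth_table(self) -> pd.DataFrame:
        """Per-probe ground truth sufficient to label null/ct/age/braak probes."""
        d = self.mu_neuron - self.mu_glia
        return pd.DataFrame(
            {
                "mu_neuron": self.mu_neuron,
                "mu_glia": self.mu_glia,
                "delta_ct": d,
                "is_ct": self.is_ct,
                "ct_direction": np.where(d > 0, "hyper", np.where(d < 0, "hypo", "none")),
                "age_slope_neuron": self.age_slope_neuron,
                "age_slope_glia": self.age_slope_glia,
                "braak_effect_neuron": self.braak_effect_neuron,
                "braak_effect_glia": self.braak_effect_glia,
                "sex_effect": self.sex_effect,
            },
            index=pd.Index(self.probe_ids, name="probe_id"),
        )


def make_default_design(
    n_probes: int,
    seed: int,
    *,
    frac_ct: float = 0.12,
    frac_ct_hyper: float = 0.54,
    frac_age: float = 0.01,
    age_slope_mag: float = 0.002,
    frac_opposing: float = 0.25,
    frac_ct_age: float = 0.25,
    ct_age_converge_frac: float = 0.7,
    frac_braak: float = 0.005,
    braak_effect_mag: float = 0.02,
    frac_hypo_age: float = 0.6,
    frac_hypo_braak: float = 0.6,
    frac_sex: float = 0.01,
    sex_effect_mag: float = 0.01,
    frac_batch: float = 0.05,
    batch_effect_mag: float = 0.01,
    phi: float = 200.0,
    **kwargs,
) -> SyntheticDesign:
    """Build the default study design.

    Defaults: ~12% of probes are cell-type-different with |delta| >= 0.20
    (54% hypermethylated in neurons); disjoint 1% subsets per cell type get
    age slopes of magnitude 0.002 beta/yr (a quarter with opposing signs in
    the other fraction; predominantly hypomethylating); a quarter of the
    ct-different probes additionally carry cell-type-specific age slopes,
    70% of which point toward the other fraction's level (neuron-glia
    differences converging with age); 0.5% subsets per cell type get Braak
    effects of 0.02 beta/stage.  ``kwargs`` pass through to
    :class:`SyntheticDesign` (phi, age range, proportion model, ...).
    """
    if n_probes < 100:
        raise ConfigError("need at least 100 probes")
    rng = np.random.default_rng(seed)
    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])

    # bimodal baseline typical of array methylomes
    comp = rng.random(n_probes)
    mu = np.where(
        comp < 0.4,
        rng.uniform(0.03, 0.20, n_probes),
        np.where(comp < 0.8, rng.uniform(0.80, 0.97, n_probes), rng.uniform(0.20, 0.80, n_probes)),
    )
    mu_neuron = mu.copy()
    mu_glia = mu.copy()

    ct = rng.random(n_probes) < frac_ct
    n_ct = int(ct.sum())
    delta = rng.uniform(CT_DELTA, 0.45, n_ct)
    low = rng.uniform(0.03, 0.97 - delta)
    hyper = rng.random(n_ct) < frac_ct_hyper
    mu_neuron[ct] = np.where(hyper, low + delta, low)
    mu_glia[ct] = np.where(hyper, low, low + delta)

    age_slope_neuron = np.zeros(n_probes)
    age_slope_glia = np.zeros(n_probes)
    non_ct = np.flatnonzero(~ct)
    pool = rng.permutation(non_ct)
    n_age = int(round(frac_age * n_probes))
    neuron_age = pool[:n_age]
    glia_age = pool[n_age : 2 * n_age]
    sign_n = np.where(rng.random(n_age) < frac_hypo_age, -1.0, 1.0)
    sign_g = np.where(rng.random(n_age) < frac_hypo_age, -1.0, 1.0)
    age_slope_neuron[neuron_age] = sign_n * age_slope_mag
    age_slope_glia[glia_age] = sign_g * age_slope_mag
    opp_n = neuron_age[rng.random(n_age) < frac_opposing]
    opp_g = glia_age[rng.random(n_age) < frac_opposing]
    age_slope_glia[opp_n] = -age_slope_neuron[opp_n]
    age_slope_neuron[opp_g] = -age_slope_glia[opp_g]

    # age-dynamic ct probes: opposing slopes in the two fractions, with the
    # neuron-glia difference predominantly converging over lifetime
    ct_idx = np.flatnonzero(ct)
    ct_age = ct_idx[rng.random(n_ct) < frac_ct_age]
    converge = np.where(rng.random(len(ct_age)) < ct_age_converge_frac, 1.0, -1.0)
    d_sign = np.sign(mu_neuron[ct_age] - mu_glia[ct_age])
    age_slope_neuron[ct_age] = -converge * d_sign * age_slope_mag
    age_slope_glia[ct_age] = converge * d_sign * age_slope_mag

    braak_effect_neuron = np.zeros(n_probes)
    braak_effect_glia = np.zeros(n_probes)
    n_braak = int(round(frac_braak * n_probes))
    neuron_braak = pool[2 * n_age : 2 * n_age + n_braak]
    glia_braak = pool[2 * n_age + n_braak : 2 * n_age + 2 * n_braak]
    braak_effect_neuron[neuron_braak] = (
        np.where(rng.random(n_braak) < frac_hypo_braak, -1.0, 1.0) * braak_effect_mag
    )
    braak_effect_glia[glia_braak] = (
        np.where(rng.random(n_braak) < frac_hypo_braak, -1.0, 1.0) * braak_effect_mag
    )

    sex_effect = np.zeros(n_probes)
    sex_probes = rng.random(n_probes) < frac_sex
    sex_effect[sex_probes] = np.where(rng.random(int(sex_probes.sum())) < 0.5, -1, 1) * sex_effect_mag

    batch2 = np.zeros(n_probes)
    batch_probes = rng.random(n_probes) < frac_batch
    batch2[batch_probes] = (
        np.where(rng.random(int(batch_probes.sum())) < 0.5, -1, 1) * batch_effect_mag
    )
    batch_effects = {"b1": np.zeros(n_probes), "b2": batch2}

    return SyntheticDesign(
        probe_ids=probe_ids,
        mu_neuron=np.clip(mu_neuron, 0.01, 0.99),
        mu_glia=np.clip(mu_glia, 0.01, 0.99),
        age_slope_neuron=age_slope_neuron,
        age_slope_glia=age_slope_glia,
        braak_effect_neuron=braak_effect_neuron,
        braak_effect_glia=braak_effect_glia,
        sex_effect=sex_effect,
        batch_effects=batch_effects,
        phi=phi,
        seed=seed,
        **kwargs,
    )


def null_design(n_probes: int, seed: int, **kwargs) -> SyntheticDesign:
    """Design with no planted effects of any kind (global null)."""
    return make_default_design(
        n_probes, seed, frac_ct=0.0, frac_age=0.0, frac_ct_age=0.0,
        frac_braak=0.0, frac_sex=0.0, frac_batch=0.0, **kwargs,
    )


# ---------------------------------------------------------------------------
# cohort generation


def _sample_donors(design: SyntheticDesign, n: int, rng: np.random.Generator,
                   age_range: tuple | None = None) -> pd.DataFrame:
    lo, hi = age_range if age_range is not None else (design.age_low, design.age_high)
    age = rng.uniform(lo, hi, n)
    z_age = (age - age.mean()) / max(age.std(), 1e-12)
    rho = design.braak_age_corr
    z = rho * z_age + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    # rank-threshold the latent score into stages with the design's frequencies
    counts = np.floor(np.cumsum(design.braak_probs) * n + 0.5).astype(int)
    counts[-1] = n
    braak = np.zeros(n, dtype=int)
    order = np.argsort(z, kind="stable")
    start = 0
    for stage, stop in enumerate(counts):
        braak[order[start:stop]] = stage
        start = stop
    sex = np.array(["female", "male"])[np.arange(n) % 2]
    batch = np.array(["b1", "b2"])[(np.arange(n) // 2) % 2]
    perm = rng.permutation(n)
    return pd.DataFrame(
        {
            "age": age,
            "braak": braak,
            "sex": sex[perm],
            "batch": batch[perm],
            "diagnosis": np.where(braak <= 2, "control", "ad"),
        }
    )


def _mean_matrix(design: SyntheticDesign, fraction: str, donors: pd.DataFrame) -> np.ndarray:
    """Noise-free probes x donors mean methylation for one cell fraction."""
    mu = design.mu_neuron if fraction == "neuron" else design.mu_glia
    slope = design.age_slope_neuron if fraction == "neuron" else design.age_slope_glia
    braak_eff = design.braak_effect_neuron if fraction == "neuron" else design.braak_effect_glia
    m = (
        mu[:, None]
        + slope[:, None] * (donors["age"].to_numpy() - design.age_center)[None, :]
        + braak_eff[:, None] * donors["braak"].to_numpy()[None, :]
        + design.sex_effect[:, None] * (donors["sex"].to_numpy() == "male")[None, :]
    )
    for label, offsets in design.batch_effects.items():
        mask = (donors["batch"].to_numpy() == label)[None, :]
        m = m + np.asarray(offsets)[:, None] * mask
    return np.clip(m, 0.01, 0.99)


def _beta_noise(m: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    if phi >= 1e6:  # noise-free limit
        return m.copy()
    return rng.beta(m * phi, (1.0 - m) * phi)


def probe_annotation(design: SyntheticDesign) -> pd.DataFrame:
    """450k-style annotation: probes round-robin on chromosomes 1-22 with
    synthetic positions and region classes drawn at the array design
    proportions.  Deterministic given the design seed."""
    rng = np.random.default_rng([design.seed, 104729])
    n = design.n_probes
    chroms = np.array(AUTOSOMES)[np.arange(n) % 22]
    positions = 10_000 + (np.arange(n) // 22 + 1) * 481
    regions = rng.choice(
        list(REGION_DESIGN_PROPS), size=n, p=list(REGION_DESIGN_PROPS.values())
    )
    ann = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "gene": "",
            "region": regions,
            "autosomal": True,
        },
        index=pd.Index(design.probe_ids, name="probe_id"),
    )
    return ann


def generate_sorted_cohort(
    design: SyntheticDesign,
    n_per_fraction: int,
    seed: int | None = None,
    cohort: str = "sim",
    age_range: tuple | None = None,
):
    """Paired neuron/glia profiles for ``n_per_fraction`` donors.

    Returns ``(beta, sheet, annotation)``; each donor contributes one
    neuron and one glia sample sharing all covariates.
    """
    rng = np.random.default_rng([design.seed if seed is None else seed, 1])
    donors = _sample_donors(design, n_per_fraction, rng, age_range)
    blocks, rows = [], []
    for fraction, tag in (("neuron", "n"), ("glia", "g")):
        m = _mean_matrix(design, fraction, donors)
        blocks.append(_beta_noise(m, design.phi, rng))
        for i, d in donors.iterrows():
            rows.append(
                {
                    "sample_id": f"{cohort}_d{i:03d}_{tag}",
                    "cohort": cohort,
                    "cell_fraction": fraction,
                    "age": d["age"],
                    "sex": d["sex"],
                    "braak": int(d["braak"]),
                    "diagnosis": d["diagnosis"],
                    "batch": d["batch"],
                }
            )
    sheet = validate_sample_sheet(pd.DataFrame(rows).set_index("sample_id"))
    beta = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(design.probe_ids, name="probe_id"),
        columns=sheet.index,
    )
    return beta, sheet, probe_annotation(design)


def generate_bulk_cohort(
    design: SyntheticDesign,
    n: int,
    seed: int | None = None,
    cohort: str = "sim_bulk",
):
    """Bulk mixtures: per sample, neuronal weight ``w`` from the proportion
    model plus Gaussian jitter; bulk mean = w*m_neuron + (1-w)*m_glia.

    Returns ``(beta, sheet)``; the sheet records ``true_neuron_prop``.
    """
    rng = np.random.default_rng([design.seed if seed is None else seed, 2])
    donors = _sample_donors(design, n, rng)
    w = design.w0 + design.w_age * donors["age"].to_numpy() + design.w_braak * donors["braak"].to_numpy()
    w = np.clip(w + rng.normal(0.0, design.w_jitter_sd, n), 0.0, 1.0)
    m = w[None, :] * _mean_matrix(design, "neuron", donors) + (1 - w)[None, :] * _mean_matrix(
        design, "glia", donors
    )
    vals = _beta_noise(np.clip(m, 0.01, 0.99), design.phi, rng)
    rows = pd.DataFrame(
        {
            "cohort": cohort,
            "cell_fraction": "bulk",
            "age": donors["age"].to_numpy(),
            "sex": donors["sex"].to_numpy(),
            "braak": donors["braak"].to_numpy(),
            "diagnosis": donors["diagnosis"].to_numpy(),
            "batch": donors["batch"].to_numpy(),
            "true_neuron_prop": w,
        },
        index=pd.Index([f"{cohort}_s{i:03d}" for i in range(n)], name="sample_id"),
    )
    sheet = validate_sample_sheet(rows)
    beta = pd.DataFrame(vals, index=pd.Index(design.probe_ids, name="probe_id"), columns=sheet.index)
    return beta, sheet


def with_age_window(design: SyntheticDesign, low: float, high: float) -> SyntheticDesign:
    """Copy of the design restricted to an age window (centre unchanged)."""
    if high <= low:
        raise ConfigError("empty age window")
    return replace(design, age_low=low, age_high=high)
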