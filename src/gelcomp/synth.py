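"""Synthetic rheology and titration data with known ground truth.

Every fitting stage in the package has a matching generator here, so
parameter-recovery tests never need measurement files:

* single-mode Maxwell frequency sweeps
  G'  = Gp (w tau)^2 / (1 + (w tau)^2),  G'' = Gp (w tau) / (1 + (w tau)^2)
  — crossover exactly at w tau = 1;
* stretched-exponential (KWW) stress relaxation curves;
* modulus titrations produced by the forward competitive-inhibition
  chain.

Noise is multiplicative Gaussian (y -> y * (1 + sd * z)), mimicking the
dominant relative calibration error of rheometers; default sd = 5%.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import BindingSystem, NetworkSpec
from .elasticity import Convention, ElasticModel, predict_titration
from .errors import ValidationError
from .inverse import TitrationTable
from .relaxation import FrequencySweep, StressRelaxationCurve

__all__ = [
    "SyntheticSpec",
    "maxwell_sweep",
    "kww_curve",
    "titration_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Noise model and seed shared by all generators."""

    noise_sd: float = 0.05
    seed: int = 0
    noise_model: str = "multiplicative_gaussian"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.noise_model != "multiplicative_gaussian":
            raise ValidationError(f"unknown noise model {self.noise_model!r}")

    def perturb(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.noise_sd == 0.0:
            return np.asarray(values, dtype=float).copy()
        noisy = values * (1.0 + self.noise_sd * rng.standard_normal(values.shape))
        return np.clip(noisy, 0.0, None)  # moduli cannot go negative


def maxwell_sweep(g_p: float, tau: float,
                  spec: SyntheticSpec = SyntheticSpec(noise_sd=0.0),
                  omega: np.ndarray | None = None) -> FrequencySweep:
    """Single-mode Maxwell frequency sweep, optionally noisy."""
    if g_p <= 0 or tau <= 0:
        raise ValidationError("g_p and tau must be > 0")
    if omega is None:
        omega = np.logspace(-2, 2, 49) / tau  # brackets the crossover
    omega = np.asarray(omega, dtype=float)
    rng = np.random.default_rng(spec.seed)
    wt = omega * tau
    g_storage = g_p * wt ** 2 / (1.0 + wt ** 2)
    g_loss = g_p * wt / (1.0 + wt ** 2)
    return FrequencySweep(omega=omega,
                          g_storage=spec.perturb(g_storage, rng),
                          g_loss=spec.perturb(g_loss, rng))


def kww_curve(g0: float, tau: float, beta: float = 1.0,
              spec: SyntheticSpec = SyntheticSpec(noise_sd=0.0),
              time: np.ndarray | None = None) -> StressRelaxationCurve:
    """Stretched-exponential stress relaxation curve, optionally noisy."""
    if g0 <= 0 or tau <= 0:
        raise ValidationError("g0 and tau must be > 0")
    if not 0.0 < beta <= 1.0:
        raise ValidationError("beta must lie in (0, 1]")
    if time is None:
        time = np.logspace(-2, np.log10(20.0), 80) * tau
    time = np.asarray(time, dtype=float)
    rng = np.random.default_rng(spec.seed)
    g_t = g0 * np.exp(-np.power(time / tau, beta))
    return StressRelaxationCurve(time=time, g_t=spec.perturb(g_t, rng), g0=g0)


def titration_dataset(binding: BindingSystem, network: NetworkSpec,
                      conc_grid: np.ndarray,
                      spec: SyntheticSpec = SyntheticSpec(),
                      convention: Convention | str = Convention.BONDED_ARM,
                      model: ElasticModel | str = ElasticModel.PHANTOM,
                      g_uninhibited: float | None = None,
                      ) -> tuple[TitrationTable, dict]:
    """Noisy modulus titration from the forward chain, with ground truth.

    Moduli are reported on the normalized scale unless ``g_uninhibited``
    (Pa) is given as an absolute anchor.  Returns the table together
    with a ground-truth dict recording the generating parameters and
    the noiseless curve, for recovery tests.
    """
    preds = predict_titration(binding, network, conc_grid,
                              convention=convention, model=model)
    clean = np.array([pr.g_normalized for pr in preds])
    scale = 1.0 if g_uninhibited is None else float(g_uninhibited)
    rng = np.random.default_rng(spec.seed)
    noisy = spec.perturb(clean * scale, rng)
    table = TitrationTable(conc=np.asarray(conc_grid, dtype=float),
                           g_measured=noisy,
                           g_uninhibited=None if g_uninhibited is None else scale)
    truth = {
        "ka_xl": binding.ka_xl,
        "ka_c": binding.ka_c,
        "n_xl": network.n_xl,
        "functionality": network.functionality,
        "convention": str(Convention(convention).value),
        "model": str(ElasticModel(model).value),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "g_clean_normalized": clean,
    }
    return table, truth
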