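"""Synthetic descriptor-space screens and the packaged printed fixtures.

The original amino-acid training set and the solver that produced the
descriptor values are not available, so model-level behaviour is
exercised on synthetic screens: pair feature vectors are drawn from two
multivariate-normal classes (COAM / not COAM) with shared covariance,
then decomposed into per-component properties and pair energies such
that re-assembling descriptors reproduces the drawn vectors exactly.

Default conditions place the class separation entirely in the two
excess-enthalpy coordinates, three within-class standard deviations in
each (centroid Mahalanobis distance 4.24), mimicking the clean
two-latent-variable separation real screens display; the remaining
features are class-uninformative noise on pharmaceutically plausible
scales.  Decomposition on melting is a
wet-lab phenomenon and is never generated synthetically.

The two printed validation screens (seven comelt systems with known
outcomes, and thirteen predicted-then-tested systems with continuous
COAM values) ship as packaged CSV fixtures and load through the same
I/O path as user data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .errors import ConfigError
from .io import read_component_table, read_pair_table
from .records import ComponentRecord, OutcomeLabel, PairRecord, Role, ScreenTable

#: Fixed feature order of the generated vectors (matches descriptors.FEATURE_ORDER).
_FEATURES = ("avg_mw", "sum_hbd_minus_hba", "dh_mix", "dh_hb", "d_delta_h", "d_mu")

_DEFAULT_NOTCOAM = (320.0, -4.0, 0.20, -0.20, 4.0, 1.0)
_DEFAULT_COAM = (320.0, -4.0, -1.30, -1.70, 4.0, 1.0)
#: Per-feature SDs: MW g/mol, counts, kcal/mol x2, MPa^0.5, kcal/mol.
_DEFAULT_SD = (60.0, 2.0, 0.5, 0.5, 3.0, 1.5)


def _default_cov() -> np.ndarray:
    return np.diag(np.square(_DEFAULT_SD))


@dataclass
class SyntheticConfig:
    """Conditions for one synthetic screen.

    The default centroids differ only in ΔH_mix and ΔH_hb (by three
    class-conditional SDs each, with mixing made energetically
    favourable for the COAM class).
    """

    n_pairs: int = 60
    class_balance: float = 0.5
    coam_centroid: tuple = _DEFAULT_COAM
    notcoam_centroid: tuple = _DEFAULT_NOTCOAM
    covariance: Optional[np.ndarray] = None
    seed: int = 0
    feature_set: str = "six_feature"
    mw_range: tuple = (150.0, 600.0)

    def __post_init__(self) -> None:
        if self.n_pairs < 4:
            raise ConfigError("n_pairs must be at least 4")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigError("class_balance must be strictly between 0 and 1")
        if self.feature_set not in ("six_feature", "five_feature_no_mu"):
            raise ConfigError(f"unknown feature_set '{self.feature_set}'")
        if self.covariance is None:
            self.covariance = _default_cov()
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (6, 6) or not np.allclose(cov, cov.T):
            raise ConfigError("covariance must be a symmetric 6x6 matrix")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ConfigError("covariance must be positive-definite") from None
        self.covariance = cov
        lo, hi = self.mw_range
        if not 0 < lo < hi:
            raise ConfigError("mw_range must satisfy 0 < low < high")

    def describe(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "class_balance": self.class_balance,
            "coam_centroid": list(self.coam_centroid),
            "notcoam_centroid": list(self.notcoam_centroid),
            "covariance_diag": np.diag(self.covariance).tolist(),
            "seed": self.seed,
            "feature_set": self.feature_set,
        }


def _split_counts(s: int, rng: np.random.Generator) -> tuple[int, int, int, int]:
    """Integer donor/acceptor counts realising Σ(HBD-HBA) = s.

    The coformer is lactam-like (no donors, two acceptors); the API
    absorbs the remainder plus a small random common offset.
    """
    h2d, h2a = 0, 2
    need = s - (h2d - h2a)
    k = int(rng.integers(0, 3))
    if need >= 0:
        return need + k, k, h2d, h2a
    return k, k - need, h2d, h2a


def generate_training_screen(config: SyntheticConfig) -> ScreenTable:
    """Draw a labelled synthetic screen from the two-class feature model.

    The Σ(HBD-HBA) coordinate is rounded to the nearest integer (it is a
    count difference); every other coordinate is carried exactly, so
    descriptor assembly on the generated components and energies
    reproduces the drawn feature vectors to machine precision.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    n_coam = int(round(n * config.class_balance))
    n_coam = min(max(n_coam, 1), n - 1)
    labels = np.array([OutcomeLabel.COAM] * n_coam + [OutcomeLabel.NOT_COAM] * (n - n_coam))
    rng.shuffle(labels)

    pairs: list[PairRecord] = []
    for i, label in enumerate(labels):
        centroid = (
            config.coam_centroid if label is OutcomeLabel.COAM else config.notcoam_centroid
        )
        f = rng.multivariate_normal(np.asarray(centroid, float), config.covariance)
        f[1] = round(f[1])
        avg_mw = max(f[0], config.mw_range[0] / 2)
        delta = min(rng.uniform(10.0, 60.0), 0.5 * avg_mw)
        h1d, h1a, h2d, h2a = _split_counts(int(f[1]), rng)
        dh_base = rng.uniform(5.0, 15.0)
        shift = max(0.0, -(dh_base + f[4]))
        mu_cof = rng.normal(-5.0, 2.0)
        with_mu = config.feature_set == "six_feature"
        api = ComponentRecord(
            name=f"api{i:03d}",
            role=Role.API,
            mw=avg_mw + delta,
            hbd=h1d,
            hba=h1a,
            delta_h_hansen=dh_base + f[4] + shift,
            mu=(mu_cof + f[5]) if with_mu else None,
        )
        cof = ComponentRecord(
            name=f"cof{i:03d}",
            role=Role.COFORMER,
            mw=avg_mw - delta,
            hbd=h2d,
            hba=h2a,
            delta_h_hansen=dh_base + shift,
            mu=mu_cof if with_mu else None,
        )
        pairs.append(
            PairRecord(
                api=api,
                coformer=cof,
                dh_mix=f[2],
                dh_hb=f[3],
                experimental_label=label,
                label_short=f"S{i:03d}",
            )
        )
    provenance = {
        "source": "coamscreen.synthetic.generate_training_screen",
        "hbd_hba_convention": "Lipinski (N/O acceptors, N-H/O-H donors)",
        "count_feature_rounded": True,
        **config.describe(),
    }
    return ScreenTable(pairs=pairs, provenance=provenance)


def generate_component_properties(
    config: SyntheticConfig, n: Optional[int] = None
) -> list[ComponentRecord]:
    """Standalone plausible component draws (no pair-feature targets).

    Molecular weights are uniform over ``config.mw_range``; donor and
    acceptor counts are Poisson (means 2 and 4); δh is folded normal
    around 8 MPa^0.5 and μ normal around -5 kcal/mol.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs if n is None else n
    records = []
    for i in range(n):
        for role, prefix in ((Role.API, "api"), (Role.COFORMER, "cof")):
            records.append(
                ComponentRecord(
                    name=f"{prefix}{i:03d}",
                    role=role,
                    mw=float(rng.uniform(*config.mw_range)),
                    hbd=int(rng.poisson(2)),
                    hba=int(rng.poisson(4)),
                    delta_h_hansen=float(abs(rng.normal(8.0, 3.0))),
                    mu=float(rng.normal(-5.0, 2.0)),
                )
            )
    return records


def _load_fixture(pair_file: str, source: str) -> ScreenTable:
    data = resources.files("coamscreen.data")
    with resources.as_file(data.joinpath("screen_components.csv")) as p:
        components = read_component_table(p)
    with resources.as_file(data.joinpath(pair_file)) as p:
        return read_pair_table(
            p,
            components,
            provenance={
                "source": source,
                "hbd_hba_convention": "Lipinski (N/O acceptors, N-H/O-H donors)",
            },
        )


def fixture_prior_screen() -> ScreenTable:
    """The seven-system comelt screen with known outcomes and predictions.

    Three systems were experimentally coamorphous (carbamazepine,
    carisoprodol, valsartan); the model predicted COAM only for
    valsartan, so five of seven calls are correct.
    """
    return _load_fixture("prior_screen_pairs.csv", "prior bisVCap comelt screen (7 APIs)")


def fixture_new_screen() -> ScreenTable:
    """The thirteen-system predictive screen with printed COAM values.

    Ten pairs carry a continuous COAM value at or above 0.5 (predicted
    coamorphous); famotidine, mebendazole and piroxicam decomposed on
    melting; paracetamol formed a COAM phase despite a 0.450 value.
    """
    return _load_fixture("new_screen_pairs.csv", "predictive bisVCap screen (13 APIs)")
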