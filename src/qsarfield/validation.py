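"""External predictivity battery and Y-randomization.

A QSAR model that cross-validates well can still predict poorly outside its
training set, so external test-set predictions are screened with the
regression-through-origin battery popularised by Golbraikh and Tropsha.
With Ya the experimental and Yp the predicted test activities:

    R^2        squared Pearson correlation of Ya and Yp
    k          = sum(Ya*Yp) / sum(Yp^2)       slope, Yp as abscissa
    k'         = sum(Ya*Yp) / sum(Ya^2)       slope, Ya as abscissa
    R0^2       = 1 - sum((Ya - k*Yp)^2)  / sum((Ya - mean(Ya))^2)
    R0'^2      = 1 - sum((Yp - k'*Ya)^2) / sum((Yp - mean(Yp))^2)
    rm^2       = R^2 * (1 - sqrt(R^2 - R0^2))    (difference clamped at 0)

plus the overall external coefficient

    Rpred^2 = (SD - PRESS) / SD,   SD = sum((Ya - training mean)^2).

The acceptance thresholds (R^2 > 0.6; 0.85 < k, k' < 1.15;
(R^2-R0^2)/R^2 < 0.1 or the primed analogue; |R0^2 - R0'^2| < 0.3;
rm^2 > 0.5) are evaluated as strict inequalities.

Y-randomization refits the identical modelling recipe after shuffling the
activities; a robust model collapses (q^2 near or below zero) on every
shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExternalValidationReport",
    "YRandomizationReport",
    "rpred2",
    "rm_squared",
    "external_battery",
    "tropsha_conditions",
    "y_randomization",
]


@dataclass
class ExternalValidationReport:
    r2: float
    k: float
    k_prime: float
    r02: float
    r02_prime: float
    rm2: float
    rpred2: float | None = None
    sd: float | None = None
    press: float | None = None
    condition_verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def c4a(self) -> float:
        """(R^2 - R0^2)/R^2 — closeness of the through-origin fit (Yp as X)."""
        return (self.r2 - self.r02) / self.r2

    @property
    def c4b(self) -> float:
        """(R^2 - R0'^2)/R^2 — closeness with the roles swapped."""
        return (self.r2 - self.r02_prime) / self.r2

    @property
    def c5(self) -> float:
        """|R0^2 - R0'^2| — asymmetry of the two through-origin fits."""
        return abs(self.r02 - self.r02_prime)


@dataclass
class YRandomizationReport:
    n_shuffles: int
    seed: int
    q2_r2_pairs: list[tuple[float, float]]

    @property
    def mean_q2(self) -> float:
        return float(np.mean([p[0] for p in self.q2_r2_pairs]))

    @property
    def max_r2(self) -> float:
        return float(np.max([p[1] for p in self.q2_r2_pairs]))


def rpred2(y_test, y_pred, y_train_mean: float) -> float:
    """External predictive coefficient (SD - PRESS)/SD."""
    ya = np.asarray(y_test, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if ya.shape != yp.shape or ya.size < 2:
        raise ValueError("need equal-length vectors of at least 2 test compounds")
    sd = float(np.sum((ya - y_train_mean) ** 2))
    if sd == 0.0:
        raise ValueError("SD is zero: test activities all equal the training mean")
    press = float(np.sum((yp - ya) ** 2))
    return (sd - press) / sd


def rm_squared(r2: float, r02: float) -> float:
    """rm^2 = R^2 (1 - sqrt(R^2 - R0^2)); the difference is clamped at zero
    because a through-origin fit can numerically beat the centered one."""
    return r2 * (1.0 - np.sqrt(max(r2 - r02, 0.0)))


def external_battery(ya, yp) -> ExternalValidationReport:
    """Compute the full through-origin battery from test-set vectors."""
    ya = np.asarray(ya, dtype=float)
    yp = np.asarray(yp, dtype=float)
    if ya.shape != yp.shape or ya.size < 3:
        raise ValueError("need equal-length vectors of at least 3 test compounds")
    if np.var(ya) == 0.0 or np.var(yp) == 0.0:
        raise ValueError("constant input vector")
    ya_c = ya - ya.mean()
    yp_c = yp - yp.mean()
    r2 = float((ya_c @ yp_c) ** 2 / ((ya_c @ ya_c) * (yp_c @ yp_c)))
    k = float(np.sum(ya * yp) / np.sum(yp * yp))
    k_prime = float(np.sum(ya * yp) / np.sum(ya * ya))
    r02 = float(1.0 - np.sum((ya - k * yp) ** 2) / np.sum(ya_c**2))
    r02_prime = float(1.0 - np.sum((yp - k_prime * ya) ** 2) / np.sum(yp_c**2))
    rm2 = float(rm_squared(r2, r02))
    report = ExternalValidationReport(
        r2=r2, k=k, k_prime=k_prime, r02=r02, r02_prime=r02_prime, rm2=rm2
    )
    report.condition_verdicts = tropsha_conditions(report)
    return report


DEFAULT_THRESHOLDS = {
    "r2_min": 0.6,
    "k_low": 0.85,
    "k_high": 1.15,
    "rel_r02_max": 0.1,
    "r02_gap_max": 0.3,
    "rm2_min": 0.5,
}


def tropsha_conditions(
    report: ExternalValidationReport, thresholds: dict | None = None
) -> dict[str, bool]:
    """Strict-inequality verdicts for the external-validation conditions.

    Overall acceptance requires condition 1, (3a or 3b), (4a or 4b), 5 and 6;
    conditions 2a/2b ("R0^2 close to R^2") are quantified by 4a/4b.
    """
    t = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    v = {
        "1": bool(report.r2 > t["r2_min"]),
        "3a": bool(t["k_low"] < report.k < t["k_high"]),
        "3b": bool(t["k_low"] < report.k_prime < t["k_high"]),
        "4a": bool(report.c4a < t["rel_r02_max"]),
        "4b": bool(report.c4b < t["rel_r02_max"]),
        "5": bool(report.c5 < t["r02_gap_max"]),
        "6": bool(report.rm2 > t["rm2_min"]),
    }
    v["overall"] = (
        v["1"] and (v["3a"] or v["3b"]) and (v["4a"] or v["4b"]) and v["5"] and v["6"]
    )
    return v


def y_randomization(
    x, y, fit_recipe, n_shuffles: int = 10, seed: int = 0
) -> YRandomizationReport:
    """Refit after shuffling the response, ``n_shuffles`` times.

    ``fit_recipe(x, y_shuffled) -> (q2, r2)`` must rerun the identical
    modelling protocol, including component-count re-selection.  Shuffles are
    true permutations (without replacement) from a seeded generator.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be at least 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    pairs = []
    for s in range(n_shuffles):
        y_perm = y[rng.permutation(len(y))]
        try:
            q2, r2 = fit_recipe(x, y_perm)
        except Exception as exc:  # annotate with the shuffle index
            raise RuntimeError(f"fit failed on shuffle {s + 1}: {exc}") from exc
        pairs.append((float(q2), float(r2)))
    return YRandomizationReport(n_shuffles=n_shuffles, seed=seed, q2_r2_pairs=pairs)
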