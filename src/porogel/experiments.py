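"""The full simulation campaign and variant-agreement metrics.

The campaign runs every combination in
``{chandran x 0.30%} + {busby x {0.20%, 0.30%, 0.40%}}`` with the three
Neo-Hookean variants — 12 ramp-hold confined-compression simulations — and
summarises each run by its peak and end-of-hold bottom effective stress.
For every protocol/material cell the three unordered variant pairs are
compared through the symmetric percent difference
``100 |a - b| / ((a + b)/2)``, separately for the peak and the end value,
and the report aggregates those 24 numbers into the averages of interest:
overall, per variant pair, per statistic, and with the incompressible-form
variant excluded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .constitutive import HydrogelMaterial, ModelVariant, table1_materials
from .errors import SolverError, ValidationError
from .poro1d import LoadingProtocol, SolverSettings, StressHistory, simulate

__all__ = [
    "CAMPAIGN_CELLS",
    "bundled_protocols",
    "percent_difference",
    "VariantComparison",
    "run_campaign",
]

logger = logging.getLogger(__name__)

#: (protocol key, material key) cells of the simulation campaign
CAMPAIGN_CELLS: tuple[tuple[str, str], ...] = (
    ("chandran", "c030"),
    ("busby", "c020"),
    ("busby", "c030"),
    ("busby", "c040"),
)

_MATERIAL_KEYS = ("c020", "c030", "c040")


def bundled_protocols() -> dict[str, LoadingProtocol]:
    """The two bundled ramp-hold protocols, keyed 'busby' and 'chandran'."""
    from .config import load_protocol_blocks  # local import to avoid a cycle

    return load_protocol_blocks()


def bundled_materials() -> dict[str, HydrogelMaterial]:
    """Bundled materials keyed 'c020', 'c030', 'c040'."""
    return dict(zip(_MATERIAL_KEYS, table1_materials()))


def percent_difference(a: float, b: float) -> float:
    """Symmetric percent difference ``100 |a - b| / (|a + b| / 2)``.

    Defined for two same-sign, nonzero quantities; symmetric in its
    arguments, zero iff a == b.
    """
    if a == 0 or b == 0 or (a > 0) != (b > 0):
        raise ValidationError(
            "percent_difference requires two nonzero values of the same sign"
        )
    return 100.0 * abs(a - b) / (abs(a + b) / 2.0)


@dataclass
class VariantComparison:
    """Peak/end stresses for every campaign run plus pairwise differences.

    runs : one row per (protocol, material, variant) with peak_eff_kPa and
        end_eff_kPa (compressive magnitudes, kPa).
    pairwise : one row per (protocol, material, variant pair, statistic)
        with the symmetric percent difference.
    averages : named aggregations of the pairwise differences, %.
    """

    runs: pd.DataFrame
    pairwise: pd.DataFrame
    averages: dict[str, float]
    histories: dict[tuple[str, str, str], StressHistory] | None = None

    @property
    def average_difference(self) -> float:
        """Mean of all pairwise percent differences (peak and end), %."""
        return self.averages["overall"]


def _summarise(histories: dict[tuple[str, str, str], StressHistory]) -> pd.DataFrame:
    rows = [
        {
            "protocol": proto,
            "material": mat,
            "variant": var,
            "peak_eff_kPa": h.peak_effective / 1e3,
            "end_eff_kPa": h.end_effective / 1e3,
        }
        for (proto, mat, var), h in histories.items()
    ]
    return pd.DataFrame(rows)


def _pairwise_table(runs: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (proto, mat), cell in runs.groupby(["protocol", "material"], sort=False):
        by_var = cell.set_index("variant")
        for va, vb in itertools.combinations(sorted(by_var.index), 2):
            for stat in ("peak_eff_kPa", "end_eff_kPa"):
                rows.append(
                    {
                        "protocol": proto,
                        "material": mat,
                        "pair": f"{va}-{vb}",
                        "statistic": stat.removesuffix("_eff_kPa"),
                        "percent_difference": percent_difference(
                            float(by_var.loc[va, stat]), float(by_var.loc[vb, stat])
                        ),
                    }
                )
    return pd.DataFrame(rows)


def _aggregate(pairwise: pd.DataFrame) -> dict[str, float]:
    pd_col = pairwise["percent_difference"]
    out = {"overall": float(pd_col.mean())}
    for pair, grp in pairwise.groupby("pair"):
        out[f"pair_{pair}"] = float(grp["percent_difference"].mean())
    for stat, grp in pairwise.groupby("statistic"):
        out[f"{stat}_only"] = float(grp["percent_difference"].mean())
    no_nh1 = pairwise[~pairwise["pair"].str.contains("NH1")]
    if len(no_nh1):
        out["excluding_NH1"] = float(no_nh1["percent_difference"].mean())
    return out


def run_campaign(
    settings: SolverSettings | None = None,
    stress_fn=None,
) -> VariantComparison:
    """Execute the 12-run campaign and compute the comparison report.

    Deterministic given ``settings``.  ``stress_fn`` (mainly for testing)
    replaces the constitutive callback of *all* variants when given, which
    must drive every pairwise difference to zero.
    """
    protocols = bundled_protocols()
    materials = bundled_materials()
    histories: dict[tuple[str, str, str], StressHistory] = {}
    for proto_key, mat_key in CAMPAIGN_CELLS:
        for variant in ModelVariant:
            run_variant = stress_fn if stress_fn is not None else variant
            try:
                h = simulate(
                    materials[mat_key],
                    run_variant,
                    protocols[proto_key],
                    settings,
                )
            except SolverError as exc:
                raise SolverError(
                    f"campaign run ({proto_key}, {mat_key}, {variant.value}) "
                    f"failed: {exc}"
                ) from exc
            histories[(proto_key, mat_key, variant.value)] = h
    runs = _summarise(histories)
    pairwise = _pairwise_table(runs)
    averages = _aggregate(pairwise)
    logger.info(
        "campaign complete: overall average pairwise difference %.2f%%",
        averages["overall"],
    )
    return VariantComparison(
        runs=runs, pairwise=pairwise, averages=averages, histories=histories
    )


def experiment_relative_differences(
    comparison: VariantComparison,
    experimental: pd.DataFrame,
    protocol: str,
    material: str,
) -> pd.DataFrame:
    """Peak/end percent differences of one campaign cell vs a measured curve.

    ``experimental`` must have columns ``time_s`` and ``stress_kPa``
    (compressive positive); its peak is the maximum sample and its end value
    the final sample, mirroring how the simulated summaries are taken.
    """
    for col in ("time_s", "stress_kPa"):
        if col not in experimental.columns:
            raise ValidationError(f"experimental curve lacks column {col!r}")
    exp_peak = float(experimental["stress_kPa"].max())
    exp_end = float(experimental["stress_kPa"].iloc[-1])
    cell = comparison.runs.query("protocol == @protocol and material == @material")
    if cell.empty:
        raise ValidationError(f"no campaign cell ({protocol}, {material})")
    rows = []
    for _, r in cell.iterrows():
        rows.append(
            {
                "variant": r["variant"],
                "peak_percent_difference": percent_difference(
                    r["peak_eff_kPa"], exp_peak
                ),
                "end_percent_difference": percent_difference(
                    r["end_eff_kPa"], exp_end
                ),
            }
        )
    return pd.DataFrame(rows)
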