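"""Tabular reporting of deterministic results, with JPY and USD columns."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .analysis import CEAResult
from .parameters import EconSettings, ModelParameters, save_parameters

COST_ROW_LABELS = {
    "drug_acquisition": "Drug acquisition cost",
    "ae": "AE cost",
    "hcru": "Health care resource use cost",
    "monitoring": "Monitoring cost",
}


def report_cea(result: CEAResult, settings: EconSettings) -> pd.DataFrame:
    """Pairwise results table: one row per outcome, JPY and USD columns.

    Monetary rows carry USD values (JPY divided by the reporting exchange
    rate); time-denominated rows leave the USD columns empty. The lost
    income row appears only under the societal perspective.
    """
    fx = settings.yen_per_usd
    ab, soc = result.arms["abrocitinib"], result.arms["soc"]
    societal = result.perspective == "societal"

    def money(label, a_val, s_val, inc=None):
        return {"quantity": label,
                "abrocitinib_jpy": a_val, "soc_jpy": s_val,
                "incremental_jpy": inc,
                "abrocitinib_usd": None if a_val is None else a_val / fx,
                "soc_usd": None if s_val is None else s_val / fx,
                "incremental_usd": None if inc is None else inc / fx}

    def plain(label, a_val, s_val, inc=None):
        return {"quantity": label,
                "abrocitinib_jpy": a_val, "soc_jpy": s_val,
                "incremental_jpy": inc,
                "abrocitinib_usd": None, "soc_usd": None,
                "incremental_usd": None}

    total_a = ab.total_societal if societal else ab.total_payer
    total_s = soc.total_societal if societal else soc.total_payer

    rows = [
        plain("Total LY", ab.ly, soc.ly),
        plain("Total QALY", ab.qaly, soc.qaly),
        plain("Total years in response", ab.years_in_response,
              soc.years_in_response),
        plain("Years receiving subsequent treatment", ab.years_subsequent,
              soc.years_subsequent),
        money("Total cost", total_a, total_s),
    ]
    for cat, label in COST_ROW_LABELS.items():
        rows.append(money(label, ab.costs[cat], soc.costs[cat]))
    if societal:
        rows.append(money("Lost income", ab.lost_income, soc.lost_income))
    rows.append(plain("Incremental QALY", None, None, result.inc_qaly))
    rows.append(money("Incremental cost", None, None, result.inc_cost))
    rows.append(money("ICER (per QALY)", None, None, result.icer))

    df = pd.DataFrame(rows)
    for col in ("abrocitinib_jpy", "soc_jpy", "incremental_jpy"):
        df[col] = df[col].astype(float)
    return df


def format_report(df: pd.DataFrame) -> pd.DataFrame:
    """Round for display: JPY to the yen, USD to one decimal, times to 2 dp."""
    out = df.copy()
    monetary = out["abrocitinib_usd"].notna() | out["incremental_usd"].notna()
    for col in ("abrocitinib_jpy", "soc_jpy", "incremental_jpy"):
        out.loc[monetary, col] = out.loc[monetary, col].round(0)
        out.loc[~monetary, col] = out.loc[~monetary, col].round(2)
    for col in ("abrocitinib_usd", "soc_usd", "incremental_usd"):
        out[col] = out[col].astype(float).round(1)
    return out


def config_hash(p: ModelParameters) -> str:
    return hashlib.sha256(save_parameters(p).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    life_table_source: str
    seed: int | None
    perspective: str
    version: str
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def make_manifest(p: ModelParameters, life_table_source: str,
                  seed: int | None, perspective: str) -> RunManifest:
    from datetime import datetime, timezone
    return RunManifest(
        config_hash=config_hash(p),
        life_table_source=life_table_source,
        seed=seed,
        perspective=perspective,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
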