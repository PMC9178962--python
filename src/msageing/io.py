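"""Stable file formats, run configuration and provenance metadata.

All result CSVs are self-describing: a ``# key: value`` comment header
carries the parcellation hash, config hash, seed and the convention flags
(deviation sign, gap sign, FDR method) that shaped the numbers below it.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import FEATURE_NAMES
from .parcellation import Parcellation

__all__ = ["read_feature_table", "write_feature_table", "read_regional_ms",
           "write_regional_ms", "write_with_meta", "read_with_meta",
           "RunConfig", "load_config", "save_config"]


# ---------------------------------------------------------------------------
# feature tables (long / wide)
# ---------------------------------------------------------------------------

def read_feature_table(path, parcellation: Parcellation | None = None
                       ) -> pd.DataFrame:
    """Read a feature table CSV/TSV in wide or long dialect (auto-detected).

    Wide: ``subject_id, region, <7 feature columns>``.
    Long: ``subject_id, region, feature, value``.
    Validates coverage (each subject has each region exactly once), feature
    completeness and finiteness; errors cite offending rows.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep, comment="#",
                      float_precision="round_trip")
    cols = set(raw.columns)
    if {"feature", "value"} <= cols:
        unknown = set(raw["feature"].unique()) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        table = raw.pivot_table(index=["subject_id", "region"],
                                columns="feature", values="value",
                                aggfunc="first").reset_index()
        table.columns.name = None
    elif set(FEATURE_NAMES) <= cols:
        table = raw.copy()
    else:
        missing = set(FEATURE_NAMES) - cols
        raise ValueError(f"cannot detect dialect; missing columns {sorted(missing)} "
                         "and no long-format 'feature'/'value' pair")
    missing_feats = [f for f in FEATURE_NAMES if f not in table.columns]
    if missing_feats:
        raise ValueError(f"feature(s) absent from table: {missing_feats}")

    dup = table.duplicated(["subject_id", "region"])
    if dup.any():
        rows = table.index[dup].tolist()[:5]
        raise ValueError(f"duplicate subject-region rows at index {rows}")
    if parcellation is not None:
        labels = set(parcellation.labels)
        bad = ~table["region"].isin(labels)
        if bad.any():
            rows = table.index[bad].tolist()[:5]
            raise ValueError(
                f"unknown region labels at rows {rows}: "
                f"{table.loc[bad, 'region'].unique()[:5].tolist()}")
        counts = table.groupby("subject_id")["region"].nunique()
        short = counts[counts != parcellation.n_regions]
        if len(short):
            sid = short.index[0]
            have = set(table.loc[table['subject_id'] == sid, 'region'])
            gone = sorted(labels - have)[:5]
            raise ValueError(f"subject {sid!r} missing region(s) {gone}")
    vals = table[FEATURE_NAMES].to_numpy(float)
    if not np.isfinite(vals).all():
        bad_rows = table.index[~np.isfinite(vals).all(axis=1)].tolist()[:5]
        raise ValueError(f"non-finite feature values at rows {bad_rows}")
    return table[["subject_id", "region", *FEATURE_NAMES]]


#: shortest round-trip float formatting so write-then-read is bit-identical
def _ROUNDTRIP(v):
    return repr(float(v))


def write_feature_table(table: pd.DataFrame, path,
                        dialect: str = "wide") -> None:
    path = Path(path)
    if dialect == "wide":
        table.to_csv(path, index=False, float_format=_ROUNDTRIP)
    elif dialect == "long":
        long = table.melt(id_vars=["subject_id", "region"],
                          value_vars=FEATURE_NAMES,
                          var_name="feature", value_name="value")
        long.to_csv(path, index=False, float_format=_ROUNDTRIP)
    else:
        raise ValueError("dialect must be 'wide' or 'long'")


# ---------------------------------------------------------------------------
# regional MS tables and metadata-carrying CSVs
# ---------------------------------------------------------------------------

def write_regional_ms(regional_ms: pd.DataFrame, path, meta=None) -> None:
    write_with_meta(regional_ms.reset_index(), path, meta or {})


def read_regional_ms(path) -> pd.DataFrame:
    df, _ = read_with_meta(path)
    return df.set_index("subject_id")


def write_with_meta(df: pd.DataFrame, path, meta: dict) -> None:
    """CSV with '# key: value' provenance comments before the header."""
    path = Path(path)
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {meta[key]}\n")
        df.to_csv(fh, index=False, float_format=_ROUNDTRIP)


def read_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    return df, meta


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All knobs of an end-to-end run; serialized into every output."""

    seed: int = 0
    n_regions: int = 360
    # synthetic cohorts
    n_normative: int = 665
    normative_age_range: tuple = (20.0, 80.0)
    n_controls: int = 148
    n_patients: int = 183
    casecontrol_age_range: tuple = (20.0, 59.0)
    injection_delta_years: float = 10.0
    n_noise_regions: int = 48
    ms_noise_sd: float = 0.015
    feature_level: bool = False
    # trajectory stage
    degree: int = 2
    early: float = 27.0
    late: float = 60.0
    # deviation stage
    fdr_q: float = 0.01
    fdr_method: str = "bh"
    n_perm_deviations: int = 0
    age_partition: tuple = ((20, 30), (30, 35), (35, 40), (40, 45), (45, 60))
    deviation_sign: str = "observed_minus_predicted"
    # group stats / brain age / PLS
    n_perm_groups: int = 1000
    gap_convention: str = "predicted_minus_calendar"
    cv_folds: int = 5
    n_perm_pls: int = 1000
    pls_components: int = 2
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def meta(self, parcellation: Parcellation) -> dict:
        return {"config_hash": self.hash, "seed": self.seed,
                "parcellation_hash": parcellation.hash,
                "deviation_sign": self.deviation_sign,
                "gap_convention": self.gap_convention,
                "fdr_method": self.fdr_method}


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(x) for x in obj)
    return obj


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**{k: _tuplify(v) for k, v in raw.items()})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(config.to_dict(), default=str)),
                       fh, sort_keys=True)
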