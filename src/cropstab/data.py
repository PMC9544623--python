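"""Dataset schema, CSV input/output and validation.

One row of the dataset is a single effect size: a comparison between an
animal-pollinated treatment arm and an auto-pollinated control arm, each
summarised by (mean, SD, n), plus the metadata needed for moderator models
(crop, country, spatial scale, response measure, treatment type, intensity,
publication year) and a shared-control key identifying rows whose sampling
errors are correlated because they compare different treatments against the
same control group.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required CSV columns, in canonical order.
COLUMNS = [
    "publication_id", "comparison_id", "effect_id", "crop", "country",
    "scale", "response_measure", "treatment_type", "intensity", "year",
    "mean_t", "disp_t", "n_t", "mean_c", "disp_c", "n_c",
    "dispersion_kind", "shared_control_id",
]

CROPS = {"apple", "oilseed_rape", "faba_bean"}
SCALES = {"flower", "plant", "plot_or_cohort", "site"}
TREATMENT_TYPES = {"hand", "honeybee", "bumblebee", "hoverfly", "solitary", "open"}
INTENSITIES = {"high", "low", "none"}

SCHEMA_VERSION = "cropstab-schema-v1"


class SchemaError(ValueError):
    """The file does not have the documented column set."""


class ConsistencyError(ValueError):
    """Rows sharing a control group report different control summaries."""


@dataclass(frozen=True)
class ArmSummary:
    """Summary of one experimental arm's yield response.

    ``mean`` and ``sd`` are on the response-measure scale; ``n`` is the
    number of experimental units (flowers, plants, plots or sites) over
    which the mean and SD were computed.
    """

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"arm needs n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"arm sd must be non-negative, got {self.sd}")

    @property
    def cv(self) -> float:
        """Coefficient of variation sd / mean."""
        return self.sd / self.mean


@dataclass(frozen=True)
class EffectRecord:
    """One effect-size row: two arms plus metadata."""

    publication_id: str
    comparison_id: str
    effect_id: str
    crop: str
    country: str
    scale: str
    response_measure: str
    treatment_type: str
    intensity: str
    year: int
    treatment: ArmSummary
    control: ArmSummary
    shared_control_id: str


@dataclass
class Dataset:
    """An ordered collection of effect records backed by a DataFrame.

    The frame uses the canonical column set with dispersion already
    normalised to SDs (``dispersion_kind`` is ``SD`` for every row after
    validation).
    """

    frame: pd.DataFrame
    provenance: str = ""
    validation_report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def counts(self) -> dict:
        """Counts per nesting level."""
        f = self.frame
        return {
            "publications": int(f["publication_id"].nunique()),
            "comparisons": int(
                (f["publication_id"].astype(str) + ":" + f["comparison_id"].astype(str)).nunique()
            ),
            "effects": int(f["effect_id"].nunique()),
        }

    def records(self) -> Iterator[EffectRecord]:
        for row in self.frame.itertuples(index=False):
            yield EffectRecord(
                publication_id=str(row.publication_id),
                comparison_id=str(row.comparison_id),
                effect_id=str(row.effect_id),
                crop=str(row.crop),
                country=str(row.country),
                scale=str(row.scale),
                response_measure=str(row.response_measure),
                treatment_type=str(row.treatment_type),
                intensity=str(row.intensity),
                year=int(row.year),
                treatment=ArmSummary(float(row.mean_t), float(row.disp_t), int(row.n_t)),
                control=ArmSummary(float(row.mean_c), float(row.disp_c), int(row.n_c)),
                shared_control_id=str(row.shared_control_id),
            )

    def control_map(self) -> dict:
        """Map shared_control_id -> control ArmSummary (validated unique)."""
        out: dict[str, ArmSummary] = {}
        for _, row in self.frame.iterrows():
            out[str(row["shared_control_id"])] = ArmSummary(
                float(row["mean_c"]), float(row["disp_c"]), int(row["n_c"])
            )
        return out

    def subset(self, mask: pd.Series, provenance: str = "") -> "Dataset":
        return Dataset(
            self.frame.loc[mask].reset_index(drop=True),
            provenance=provenance or self.provenance,
        )


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Row-level validation; returns accepted frame and a report.

    Validation is order-independent: each row is judged on its own fields,
    then shared-control consistency is checked on the accepted set.
    """
    rejected: list[dict] = []
    warnings: list[str] = []
    keep = np.ones(len(df), dtype=bool)

    for i, row in enumerate(df.itertuples(index=False)):
        eid = str(row.effect_id)
        reasons = []
        kind = str(row.dispersion_kind)
        if kind not in {"SD", "SE"}:
            reasons.append(f"dispersion_kind must be SD or SE, got {kind!r}")
        for arm in ("t", "c"):
            mean = getattr(row, f"mean_{arm}")
            disp = getattr(row, f"disp_{arm}")
            n = getattr(row, f"n_{arm}")
            if not math.isfinite(mean) or mean <= 0:
                reasons.append(f"mean_{arm} must be > 0, got {mean}")
            if not math.isfinite(disp) or disp < 0:
                reasons.append(f"disp_{arm} must be >= 0, got {disp}")
            if not float(n).is_integer() or n < 2:
                reasons.append(f"n_{arm} must be an integer >= 2, got {n}")
            if math.isfinite(disp) and disp == 0:
                reasons.append(f"disp_{arm} is zero (log of zero SD undefined)")
                warnings.append(f"effect {eid}: zero SD in arm {arm}, row excluded")
        if reasons:
            rejected.append({"effect_id": eid, "row": i, "reasons": reasons})
            keep[i] = False

    out = df.loc[keep].copy().reset_index(drop=True)

    if out["effect_id"].duplicated().any():
        dup = out.loc[out["effect_id"].duplicated(), "effect_id"].tolist()
        raise SchemaError(f"duplicate effect_id values: {dup}")
    # each effect maps to exactly one comparison and publication by construction
    nest = out.groupby("comparison_id")["publication_id"].nunique()
    # comparison ids are allowed to repeat across publications only if treated
    # as compound keys downstream; warn so the user knows.
    if (nest > 1).any():
        warnings.append(
            "comparison_id values reused across publications; they are treated "
            "as nested via compound publication:comparison keys"
        )

    # SE -> SD normalisation, applied once at load.
    se_rows = out["dispersion_kind"] == "SE"
    if se_rows.any():
        out.loc[se_rows, "disp_t"] = out.loc[se_rows, "disp_t"] * np.sqrt(out.loc[se_rows, "n_t"])
        out.loc[se_rows, "disp_c"] = out.loc[se_rows, "disp_c"] * np.sqrt(out.loc[se_rows, "n_c"])
        out.loc[se_rows, "dispersion_kind"] = "SD"

    # shared-control consistency on the accepted set
    for scid, grp in out.groupby("shared_control_id"):
        ctl = grp[["mean_c", "disp_c", "n_c"]].drop_duplicates()
        if len(ctl) > 1:
            raise ConsistencyError(
                f"shared_control_id {scid!r}: rows report different control "
                f"summaries:\n{ctl.to_string(index=False)}"
            )

    report = {
        "rejected": rejected,
        "warnings": warnings,
        "n_input_rows": int(len(df)),
        "n_accepted_rows": int(len(out)),
    }
    for w in warnings:
        logger.warning(w)
    return out, report


def read_dataset(path, schema_options: Optional[dict] = None) -> Dataset:
    """Read and validate a dataset CSV.

    SE dispersions are converted to SDs (sd = se * sqrt(n)) at load. Rows
    failing row-level validation (non-positive mean, n < 2, zero SD) are
    excluded and listed in ``Dataset.validation_report``; pass
    ``schema_options={"strict": True}`` to raise instead. Missing columns
    raise :class:`SchemaError`; inconsistent shared-control summaries raise
    :class:`ConsistencyError`.
    """
    opts = schema_options or {}
    df = pd.read_csv(path, comment="#", dtype={"effect_id": str,
                                              "publication_id": str,
                                              "comparison_id": str,
                                              "shared_control_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df[COLUMNS]
    out, report = _validate_frame(df)
    if opts.get("strict") and report["rejected"]:
        raise ValueError(
            "rows failed validation: "
            + "; ".join(f"{r['effect_id']}: {r['reasons']}" for r in report["rejected"])
        )
    ds = Dataset(out, provenance=str(path), validation_report=report)
    report["counts"] = ds.counts()
    return ds


def write_dataset(ds: Dataset, path) -> None:
    """Write a dataset in the canonical CSV schema (with a version stamp)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        if ds.provenance:
            fh.write(f"# provenance: {ds.provenance}\n")
        ds.frame.to_csv(fh, index=False)


def write_validation_report(ds: Dataset, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ds.validation_report, fh, indent=2, sort_keys=True)


def summarize_dataset(ds: Dataset) -> pd.DataFrame:
    """Publication-level summary: mean lnCVR, mean lnRR, effect count, crop, scale.

    Mirrors the usual "publications used in analysis" table where per-publication
    effect sizes are averaged.
    """
    from . import effects  # local import to avoid a cycle

    if len(ds) == 0:
        raise ValueError("cannot summarise an empty dataset")
    cvr = effects.effect_table(ds, "lnCVR")
    rr = effects.effect_table(ds, "lnRR")
    f = ds.frame.copy()
    f["lnCVR"] = cvr["estimate"].to_numpy()
    f["lnRR"] = rr["estimate"].to_numpy()
    rows = []
    for pub, grp in f.groupby("publication_id", sort=False):
        rows.append({
            "publication_id": pub,
            "crop": grp["crop"].iloc[0],
            "country": grp["country"].iloc[0],
            "scale": grp["scale"].iloc[0],
            "lnCVR": float(grp["lnCVR"].mean()),
            "lnRR": float(grp["lnRR"].mean()),
            "effect_sizes": int(len(grp)),
        })
    return pd.DataFrame(rows)
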