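"""Reference-gRNA normalisation and experiment-level reporting.

Both gRNAs ride on one plasmid, so transfection and expression variation
scales a sample's fixed-site, variable-site and rearrangement frequencies by
a common factor. Dividing the all-sample mean fixed-site frequency by each
sample's own fixed-site frequency yields a per-sample normalisation factor;
applying it multiplicatively puts every sample on a shared ratio scale in
which the fixed site is constant, while within-sample ratios are preserved
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample raw frequencies entering normalisation.

    ``inversion_frequency`` may come from cdPCR droplet counting or from
    long-read classification (``method`` tags which); ``deletion_frequency``
    is available from long reads only and may be None.
    """

    sample_id: str
    construct_id: str
    interval_bp: int
    fixed_site_frequency: float
    variable_site_frequency: float
    inversion_frequency: float
    deletion_frequency: float | None = None
    replicate: int = 0
    is_control: bool = False
    method: str = "cdpcr"

    def __post_init__(self) -> None:
        for name in ("fixed_site_frequency", "variable_site_frequency", "inversion_frequency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class NormalisedSample:
    record: SampleRecord
    normalisation_factor: float
    normalised_fixed: float
    normalised_variable: float
    normalised_inversion: float
    normalised_deletion: float | None = None


def normalisation_factor(mean_fixed: float, sample_fixed: float) -> float:
    """Factor = all-sample mean fixed-site frequency / this sample's value."""
    if sample_fixed <= 0:
        raise ValueError("sample with zero fixed-site frequency is non-normalisable")
    return mean_fixed / sample_fixed


def reference_mean(records: list[SampleRecord]) -> float:
    """Arithmetic mean fixed-site frequency over normalisable experimental samples."""
    vals = [
        r.fixed_site_frequency
        for r in records
        if not r.is_control and r.fixed_site_frequency > 0
    ]
    if not vals:
        raise ValueError("no non-control sample with positive fixed-site frequency")
    return float(np.mean(vals))


def normalise(
    records: list[SampleRecord],
    return_excluded: bool = False,
    mean_fixed: float | None = None,
):
    """Apply reference normalisation to a sample table.

    Controls and samples with zero fixed-site frequency (inactive reference
    gRNA) are excluded from both the mean and the output. After
    normalisation every sample's fixed-site frequency equals the reference
    mean (the fixpoint of the method). Normalised values may exceed 1 for
    pathological inputs; they are reported unclamped (the scale is relative).

    ``mean_fixed`` pins the reference mean externally (e.g. an established
    value for the reference gRNA); when None it is recomputed from the
    table. With a pinned mean the normalised variable/inversion frequencies
    are exactly invariant to per-sample scaling of the raw frequencies; with
    a recomputed mean they are invariant up to the common factor by which
    the mean itself moves, while within-sample ratios are always preserved
    exactly.
    """
    if mean_fixed is None:
        mean_fixed = reference_mean(records)
    elif mean_fixed <= 0:
        raise ValueError("mean_fixed must be positive")
    out: list[NormalisedSample] = []
    excluded: list[str] = []
    for r in records:
        if r.is_control:
            continue
        if r.fixed_site_frequency <= 0:
            excluded.append(r.sample_id)
            continue
        k = normalisation_factor(mean_fixed, r.fixed_site_frequency)
        out.append(
            NormalisedSample(
                record=r,
                normalisation_factor=k,
                normalised_fixed=k * r.fixed_site_frequency,
                normalised_variable=k * r.variable_site_frequency,
                normalised_inversion=k * r.inversion_frequency,
                normalised_deletion=(
                    k * r.deletion_frequency if r.deletion_frequency is not None else None
                ),
            )
        )
    if return_excluded:
        return out, excluded
    return out


def normalised_table(samples: list[NormalisedSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        r = s.record
        rows.append(
            {
                "sample_id": r.sample_id,
                "construct_id": r.construct_id,
                "interval_bp": r.interval_bp,
                "replicate": r.replicate,
                "method": r.method,
                "raw_fixed": r.fixed_site_frequency,
                "raw_variable": r.variable_site_frequency,
                "raw_inversion": r.inversion_frequency,
                "normalisation_factor": s.normalisation_factor,
                "normalised_fixed": s.normalised_fixed,
                "normalised_variable": s.normalised_variable,
                "normalised_inversion": s.normalised_inversion,
                "normalised_deletion": s.normalised_deletion,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ExperimentReport:
    reference_mean: float
    freq_vs_size: pd.DataFrame
    freq_vs_efficiency: pd.DataFrame
    deletion_inversion: pd.DataFrame
    concordance: pd.DataFrame | None
    recovery: pd.DataFrame | None
    excluded_constructs: list[str]

    def to_dict(self) -> dict:
        return {
            "reference_mean": self.reference_mean,
            "freq_vs_size": self.freq_vs_size.to_dict(orient="records"),
            "freq_vs_efficiency": self.freq_vs_efficiency.to_dict(orient="records"),
            "deletion_inversion": self.deletion_inversion.to_dict(orient="records"),
            "concordance": (
                self.concordance.to_dict(orient="records")
                if self.concordance is not None
                else None
            ),
            "recovery": (
                self.recovery.to_dict(orient="records") if self.recovery is not None else None
            ),
            "excluded_constructs": self.excluded_constructs,
        }


def experiment_report(
    cdpcr_records: list[SampleRecord],
    longread_records: list[SampleRecord] | None = None,
    truth: dict[str, float] | None = None,
) -> ExperimentReport:
    """Normalise and summarise a full synthetic experiment.

    Emits: normalised inversion frequency vs interval size; normalised
    inversion frequency vs normalised variable-site mutation frequency (with
    the reference mean as the saturation threshold); per-construct
    deletion:inversion ratios; cdPCR-vs-long-read concordance per construct;
    and, when generative truth is supplied, per-construct recovery error.
    Constructs without any detected inversion are excluded from the
    normalised panels and listed separately.
    """
    mean_fixed = reference_mean(cdpcr_records)
    norm = normalise(cdpcr_records)
    table = normalised_table(norm)
    if table.empty:
        raise ValueError("no normalisable samples")

    per_construct = table.groupby("construct_id", sort=False).agg(
        interval_bp=("interval_bp", "first"),
        mean_norm_inversion=("normalised_inversion", "mean"),
        sd_norm_inversion=("normalised_inversion", "std"),
        mean_norm_variable=("normalised_variable", "mean"),
        n_replicates=("sample_id", "count"),
    )
    detected = per_construct["mean_norm_inversion"] > 0
    excluded_constructs = per_construct.index[~detected].tolist()
    freq_vs_size = (
        per_construct[detected]
        .reset_index()[["construct_id", "interval_bp", "mean_norm_inversion", "sd_norm_inversion", "n_replicates"]]
        .sort_values("interval_bp")
        .reset_index(drop=True)
    )
    kept = table[table["construct_id"].isin(per_construct.index[detected])]
    freq_vs_efficiency = kept[
        ["sample_id", "construct_id", "interval_bp", "normalised_variable", "normalised_inversion"]
    ].copy()
    freq_vs_efficiency["saturation_threshold"] = mean_fixed

    # deletion:inversion ratios come from records carrying a deletion channel
    del_rows = []
    pool = list(cdpcr_records) + list(longread_records or [])
    norm_all = normalise(pool)
    del_df = pd.DataFrame(
        [
            {
                "construct_id": s.record.construct_id,
                "norm_inv": s.normalised_inversion,
                "norm_del": s.normalised_deletion,
            }
            for s in norm_all
            if s.normalised_deletion is not None
        ]
    )
    for construct, grp in (
        del_df.groupby("construct_id", sort=False) if not del_df.empty else []
    ):
        mean_inv = grp["norm_inv"].mean()
        del_rows.append(
            {
                "construct_id": construct,
                "mean_norm_deletion": grp["norm_del"].mean(),
                "mean_norm_inversion": mean_inv,
                "deletion_inversion_ratio": (
                    grp["norm_del"].mean() / mean_inv if mean_inv > 0 else np.nan
                ),
            }
        )
    deletion_inversion = pd.DataFrame(
        del_rows, columns=["construct_id", "mean_norm_deletion", "mean_norm_inversion", "deletion_inversion_ratio"]
    )

    concordance = None
    if longread_records:
        lr_table = normalised_table(normalise(longread_records))
        cd = table.groupby("construct_id")["normalised_inversion"].mean()
        lr = lr_table.groupby("construct_id")["normalised_inversion"].mean()
        shared = cd.index.intersection(lr.index)
        if len(shared) == 0:
            raise ValueError(
                "no shared constructs between methods: "
                f"cdPCR={sorted(cd.index)}, long-read={sorted(lr.index)}"
            )
        concordance = pd.DataFrame(
            {
                "construct_id": shared,
                "cdpcr_norm_inversion": cd[shared].to_numpy(),
                "longread_norm_inversion": lr[shared].to_numpy(),
            }
        )
        concordance["ratio"] = (
            concordance["cdpcr_norm_inversion"] / concordance["longread_norm_inversion"]
        )
        concordance["abs_difference"] = (
            concordance["cdpcr_norm_inversion"] - concordance["longread_norm_inversion"]
        ).abs()

    recovery = None
    if truth is not None:
        unknown = sorted(set(truth) - set(table["construct_id"]))
        if unknown:
            raise ValueError(f"truth keys not present in sample table: {unknown}")
        rows = []
        for construct, true_freq in truth.items():
            est = table.loc[table["construct_id"] == construct, "normalised_inversion"].mean()
            rows.append(
                {
                    "construct_id": construct,
                    "true_frequency": true_freq,
                    "estimated_frequency": est,
                    "relative_error": (est - true_freq) / true_freq if true_freq else np.nan,
                }
            )
        recovery = pd.DataFrame(rows)

    return ExperimentReport(
        reference_mean=mean_fixed,
        freq_vs_size=freq_vs_size,
        freq_vs_efficiency=freq_vs_efficiency.reset_index(drop=True),
        deletion_inversion=deletion_inversion,
        concordance=concordance,
        recovery=recovery,
        excluded_constructs=excluded_constructs,
    )
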