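"""Multi-stage standardization of raw expression signals.

Overall signal levels on an array reflect RNA quantity and quality as
much as biology, so raw abundances are standardized in three fixed
stages before any genetic analysis:

1. z-scoring within individuals, inside decile bins of transcripts
   grouped by average log raw signal across individuals (so bright and
   dim transcripts are standardized against comparable peers);
2. per-transcript linear regression against each individual's average
   log raw signal and its square, removing residual intensity-dependent
   artifacts;
3. a rank-based inverse normal transformation across individuals per
   transcript, yielding standard-normal phenotypes suitable for
   variance-components likelihoods.

Log base is natural throughout; any other base only rescales and is
absorbed by the z-scoring.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .detection import RawExpressionStudy

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedExpression:
    """Per-transcript standard-normal expression phenotypes.

    ``values`` is samples × transcripts.  ``provenance`` records the
    bin count, the stage-2 regression coefficients and the inverse
    normal offset convention.
    """

    sample_ids: list[str]
    transcript_ids: list[str]
    values: np.ndarray
    provenance: dict

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.transcript_ids)

    def column(self, transcript: str) -> np.ndarray:
        return self.values[:, self.transcript_ids.index(transcript)]

    def write(self, matrix_path: str | Path, provenance_path: str | Path | None = None) -> None:
        self.frame().to_csv(matrix_path, sep="\t", index_label="sample_id")
        if provenance_path is not None:
            Path(provenance_path).write_text(json.dumps(self.provenance, indent=2))


def _log_signal(study: RawExpressionStudy, transcripts: list[str]) -> np.ndarray:
    idx = {p: k for k, p in enumerate(study.probe_ids)}
    cols = np.array([idx[t] for t in transcripts])
    return np.log(study.signal[:, cols])


_SD_FLOOR = 1e-12  # log-scale sd at or below float noise counts as constant


def drop_zero_variance(logx: np.ndarray, transcripts: list[str]) -> tuple[np.ndarray, list[str]]:
    sd = logx.std(axis=0)
    keep = sd > _SD_FLOOR
    if not keep.all():
        dropped = [t for t, k in zip(transcripts, keep) if not k]
        log.warning("dropping %d zero-variance transcripts before binning", len(dropped))
        warnings.warn(
            f"dropped {len(dropped)} zero-variance transcript(s)", stacklevel=2
        )
    return logx[:, keep], [t for t, k in zip(transcripts, keep) if k]


def decile_bins(
    study: RawExpressionStudy,
    transcripts: list[str] | None = None,
    n_bins: int = 10,
) -> dict[str, int]:
    """Assign transcripts to equal-count bins of mean log raw signal.

    Transcripts are sorted by (mean log signal, transcript id) — the id
    is the deterministic tie-break — and split into ``n_bins`` bins;
    any remainder is spread one-per-bin over the lowest bins.
    """
    if transcripts is None:
        transcripts = study.noncontrol_probes()
    if len(transcripts) < 2 * n_bins:
        raise NormalizationError(
            f"need at least {2 * n_bins} transcripts for {n_bins} bins, "
            f"got {len(transcripts)}"
        )
    logx = _log_signal(study, transcripts)
    means = logx.mean(axis=0)
    order = sorted(range(len(transcripts)), key=lambda k: (means[k], transcripts[k]))
    base, rem = divmod(len(transcripts), n_bins)
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]
    bins: dict[str, int] = {}
    pos = 0
    for b, size in enumerate(sizes):
        for k in order[pos : pos + size]:
            bins[transcripts[k]] = b
        pos += size
    return bins


def within_individual_zscore(
    study: RawExpressionStudy, bins: dict[str, int]
) -> tuple[np.ndarray, list[str]]:
    """Stage 1: z-score log signals within each sample, inside each bin.

    Returns (z matrix samples × transcripts, transcript order).  The
    standard deviation uses the n-1 denominator.  A bin with zero
    variance inside some sample is an error naming both.
    """
    transcripts = sorted(bins.keys(), key=lambda t: (bins[t], t))
    logx = _log_signal(study, transcripts)
    bin_of = np.array([bins[t] for t in transcripts])
    z = np.empty_like(logx)
    for b in np.unique(bin_of):
        cols = bin_of == b
        block = logx[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd <= _SD_FLOOR):
            s = int(np.nonzero(sd[:, 0] <= _SD_FLOOR)[0][0])
            raise NormalizationError(
                f"zero within-bin variance in sample {study.sample_ids[s]!r}, bin {b}"
            )
        z[:, cols] = (block - mu) / sd
    return z, transcripts


def regress_out_signal(
    z: np.ndarray, study: RawExpressionStudy, transcripts: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 2: remove dependence on per-sample mean log signal.

    For each transcript, OLS of its z-scores on [1, m_s, m_s^2] where
    m_s is sample s's average log raw signal over non-control probes;
    returns (residual matrix, fitted coefficients 3 × transcripts).
    """
    noncontrol = study.noncontrol_probes()
    m = _log_signal(study, noncontrol).mean(axis=1)
    design = np.column_stack([np.ones_like(m), m, m * m])
    if np.linalg.matrix_rank(design) < 3:
        raise NormalizationError(
            "degenerate stage-2 design: per-sample average log signals are "
            "(nearly) constant; skip this stage for such data"
        )
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    resid = z - design @ coef
    return resid, coef


def inverse_normalize_matrix(values: np.ndarray, offset: str = "blom") -> np.ndarray:
    """Stage 3: rank-based inverse normal transform per column.

    Blom convention maps average rank r to Phi^{-1}((r - 3/8)/(n + 1/4));
    the ``mean`` alternative uses (r - 1/2)/n.  Ties share their average
    rank and therefore map to equal values.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 3:
        raise NormalizationError("inverse normalization needs at least 3 samples")
    if not np.all(np.isfinite(values)):
        raise NormalizationError("non-finite values passed to inverse normalization")
    ranks = np.apply_along_axis(rankdata, 0, values)
    if offset == "blom":
        p = (ranks - 0.375) / (n + 0.25)
    elif offset == "mean":
        p = (ranks - 0.5) / n
    else:
        raise NormalizationError(f"unknown inverse-normal offset {offset!r}")
    return ndtri(p)


def normalize_expression(
    study: RawExpressionStudy,
    transcripts: list[str] | None = None,
    n_bins: int = 10,
    offset: str = "blom",
) -> NormalizedExpression:
    """Run all three standardization stages in their fixed order."""
    if transcripts is None:
        transcripts = study.noncontrol_probes()
    logx = _log_signal(study, transcripts)
    _, transcripts = drop_zero_variance(logx, transcripts)
    bins = decile_bins(study, transcripts, n_bins=n_bins)
    z, order = within_individual_zscore(study, bins)
    resid, coef = regress_out_signal(z, study, order)
    values = inverse_normalize_matrix(resid, offset=offset)
    provenance = {
        "n_bins": n_bins,
        "offset": offset,
        "log_base": "e",
        "stage2_coefficients": {t: coef[:, k].tolist() for k, t in enumerate(order)},
    }
    return NormalizedExpression(
        sample_ids=list(study.sample_ids),
        transcript_ids=order,
        values=values,
        provenance=provenance,
    )


def read_normalized_tsv(path: str | Path) -> NormalizedExpression:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return NormalizedExpression(
        sample_ids=list(df.index.astype(str)),
        transcript_ids=list(df.columns),
        values=df.to_numpy(),
        provenance={},
    )
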