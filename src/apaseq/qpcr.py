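"""Q-RT-PCR isoform-ratio arithmetic.

Each gene is measured with two primer sets — one just upstream of the
proximal polyA site (the amplicon only exists when the short isoform is
made, because the targeted intronic sequence is spliced out otherwise) and
one upstream of a distal site.  Triplicate Ct values are collapsed to a
median after removing outliers (|Ct - median| > 2); the short/long
expression ratio is efficiency^(Ct_distal - Ct_proximal) with a perfect
doubling assumed by default (efficiency 2, i.e. the classic delta-Ct
transform); and per-sample ratios are normalized to the reference sample so
that values > 1 mean relatively more of the truncated isoform in the tumor.
"""

from __future__ import annotations

import importlib.resources
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import IsoformRatio, QpcrRecord

DEFAULT_EFFICIENCY = 2.0
OUTLIER_CT_DEVIATION = 2.0


def median_ct_with_outliers(triplicate: Sequence[float],
                            max_deviation: float = OUTLIER_CT_DEVIATION
                            ) -> tuple[float, int]:
    """Median Ct after one round of outlier removal.

    Compute the median of the 1-3 replicate values, drop values deviating
    from it by more than ``max_deviation`` cycles, and return the median of
    the survivors plus the number of values removed.  The rule is applied
    once, not iterated; the median itself always survives, so the result is
    always defined for non-empty input.
    """
    values = [float(v) for v in triplicate if v is not None and not math.isnan(float(v))]
    if not values:
        raise ValueError("no Ct values supplied")
    med = float(np.median(values))
    survivors = [v for v in values if abs(v - med) <= max_deviation]
    if not survivors:
        # only possible for an even count whose median (mean of the central
        # pair) sits > max_deviation from both; keep the median, remove none
        return med, 0
    return float(np.median(survivors)), len(values) - len(survivors)


def ct_ratio(ct_proximal: float, ct_distal: float,
             efficiency: float = DEFAULT_EFFICIENCY) -> float:
    """Short/long expression ratio from the two amplicons' Ct values:
    efficiency**(ct_distal - ct_proximal).  A lower proximal Ct (more short
    isoform) gives a ratio above 1."""
    if not (math.isfinite(ct_proximal) and math.isfinite(ct_distal)):
        raise ValueError("Ct values must be finite")
    return efficiency ** (ct_distal - ct_proximal)


def normalize_ratio_to_reference(sample_ratio: float, reference_ratio: float) -> float:
    """Sample ratio relative to the reference sample's ratio."""
    if reference_ratio == 0:
        raise ValueError("reference ratio must be non-zero")
    return sample_ratio / reference_ratio


def read_ct_csv(path) -> list[QpcrRecord]:
    """CSV with columns sample_id, gene_id, amplicon, ct1, ct2, ct3
    (blank = missing replicate)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples():
        cts = [float(v) for v in (row.ct1, row.ct2, row.ct3)
               if v is not None and not pd.isna(v)]
        records.append(QpcrRecord(sample_id=str(row.sample_id),
                                  gene_id=str(row.gene_id),
                                  amplicon=str(row.amplicon), ct_values=cts))
    return records


def isoform_ratios(records: Iterable[QpcrRecord],
                   efficiency: float = DEFAULT_EFFICIENCY
                   ) -> tuple[list[IsoformRatio], int]:
    """Per (sample, gene) short/long ratios from proximal/distal Ct records;
    also returns the total number of outlier Ct values removed."""
    medians: dict[tuple[str, str, str], float] = {}
    n_outliers = 0
    for rec in records:
        med, removed = median_ct_with_outliers(rec.ct_values)
        medians[(rec.sample_id, rec.gene_id, rec.amplicon)] = med
        n_outliers += removed
    ratios = []
    keys = sorted({(s, g) for (s, g, _a) in medians})
    for sample_id, gene_id in keys:
        try:
            prox = medians[(sample_id, gene_id, "proximal")]
            dist = medians[(sample_id, gene_id, "distal")]
        except KeyError as exc:
            raise ValueError(f"missing amplicon for {sample_id}/{gene_id}") from exc
        ratios.append(IsoformRatio(sample_id=sample_id, gene_id=gene_id,
                                   ratio=ct_ratio(prox, dist, efficiency)))
    return ratios, n_outliers


def normalize_ratio_table(ratios: pd.DataFrame, reference_sample: str) -> pd.DataFrame:
    """Divide every sample's ratios (rows = samples, columns = genes) by the
    reference sample's row; the reference row is dropped from the output."""
    if reference_sample not in ratios.index:
        raise ValueError(f"reference sample {reference_sample!r} not in table")
    ref = ratios.loc[reference_sample]
    if (ref == 0).any():
        raise ValueError("reference ratios must be non-zero")
    out = ratios.div(ref, axis=1)
    return out.drop(index=reference_sample)


def load_published_qpcr_ratios() -> pd.DataFrame:
    """Published short/long isoform qPCR expression ratios for DCC, PDZD2 and
    LRRFIP1 in the three SI-NET samples and the pituitary reference (rows =
    samples, columns = genes)."""
    with importlib.resources.files("apaseq.data").joinpath(
            "qpcr_isoform_ratios.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)


def load_primer_metadata() -> pd.DataFrame:
    """qPCR primer sets used for the three validated genes (documentation
    reference data)."""
    with importlib.resources.files("apaseq.data").joinpath(
            "qpcr_primers.csv").open() as fh:
        return pd.read_csv(fh)
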