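"""Nucleus classification from two-channel IEG focus intensities.

The analysis chain mirrors a standard two-epoch catFISH quantification:

1. mid-Z selection -- only nuclei centred in the middle 20% of the
   confocal stack are analysed, avoiding truncated nuclei at the section
   faces that would read as false negatives;
2. glia exclusion -- putative glial nuclei (small, elongated or with
   bright unstructured counterstain, and without IEG signal) are removed
   from all denominators;
3. thresholding -- per slide x region x channel intensity thresholds are
   derived from exemplar nuclei flagged as the weakest unambiguous
   positives among arena-exploring animals (home-cage animals never
   contribute);
4. classification -- each neuronal nucleus becomes negative, Homer1a+
   (epoch 1 / session A1, green channel), Arc+ (epoch 2 / session A2,
   orange-red channel) or double-positive;
5. per-region proportions per animal, the input to the ensemble
   similarity score and the group contrasts.

Boundary conventions are deterministic and documented: the mid-Z band is
half-open, and intensity exactly at threshold counts as positive.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "IEG_CLASSES",
    "select_mid_z",
    "derive_thresholds",
    "filter_glia",
    "classify_nuclei",
    "region_proportions",
    "extract_features_from_stack",
    "NucleusClassifier",
]

IEG_CLASSES = ("negative", "homer_pos", "arc_pos", "double_pos")

#: channel -> (intensity column, exemplar column, epoch label)
CHANNELS = {
    "e1": ("intensity_e1_channel", "exemplar_weakest_e1", "A1"),  # green, Homer1a
    "e2": ("intensity_e2_channel", "exemplar_weakest_e2", "A2"),  # orange/red, Arc
}

REQUIRED_COLUMNS = (
    "animal_id",
    "treatment",
    "environment",
    "region",
    "slide_id",
    "z_centroid_fraction",
    "size",
    "elongation",
    "counterstain_brightness",
    "intensity_e1_channel",
    "intensity_e2_channel",
)


class ThresholdError(ValueError):
    """Raised when a slide x region x channel group has no exemplar or a
    nucleus falls in a group without a derived threshold."""


def select_mid_z(nuclei: pd.DataFrame, band: float = 0.20) -> pd.DataFrame:
    """Mark nuclei centred in the middle ``band`` of the stack.

    A nucleus is retained when its z-centroid fraction lies in the
    half-open interval [0.5 - band/2, 0.5 + band/2).  Excluded nuclei are
    marked (``included_mid_z = False``), not dropped.
    """
    if not 0.0 < band <= 1.0:
        raise ValueError(f"band must be in (0, 1], got {band}")
    lo, hi = 0.5 - band / 2.0, 0.5 + band / 2.0
    out = nuclei.copy()
    z = out["z_centroid_fraction"].to_numpy(float)
    out["included_mid_z"] = (z >= lo) & (z < hi) if band < 1.0 else np.ones(len(out), bool)
    return out


def derive_thresholds(
    nuclei: pd.DataFrame,
    statistic: str = "min",
    quantile: float = 0.0,
) -> pd.DataFrame:
    """Per slide x region x channel intensity thresholds from exemplars.

    Exemplar nuclei are the manually flagged weakest unambiguous positives
    of arena-exploring animals; the threshold is the minimum exemplar
    intensity in the group (optionally a low quantile for robustness).
    Home-cage animals never contribute.  Thresholds are never imputed
    across regions or slides: a group that needs a threshold but has no
    exemplar raises at classification time.

    Returns a frame with columns ``slide_id, region, channel, threshold``.
    """
    if statistic not in ("min", "quantile"):
        raise ValueError("statistic must be 'min' or 'quantile'")
    exploring = nuclei[nuclei["environment"] == "A1A2"]
    rows = []
    for ch, (int_col, ex_col, _) in CHANNELS.items():
        if ex_col not in nuclei.columns:
            raise ThresholdError(f"missing exemplar column {ex_col}")
        flagged = exploring[exploring[ex_col].astype(bool)]
        for (slide, region), g in flagged.groupby(["slide_id", "region"]):
            vals = g[int_col].to_numpy(float)
            thr = float(np.min(vals)) if statistic == "min" else float(np.quantile(vals, quantile))
            rows.append({"slide_id": slide, "region": region, "channel": ch, "threshold": thr})
    if not rows:
        raise ThresholdError("no exemplar-flagged nuclei among exploring-arm animals")
    return pd.DataFrame(rows)


def _threshold_lookup(thresholds: pd.DataFrame) -> dict:
    return {
        (r.slide_id, r.region, r.channel): r.threshold
        for r in thresholds.itertuples(index=False)
    }


def _per_nucleus_thresholds(
    nuclei: pd.DataFrame, thresholds: pd.DataFrame
) -> Tuple[np.ndarray, np.ndarray]:
    lut = _threshold_lookup(thresholds)
    thr = {ch: np.empty(len(nuclei)) for ch in CHANNELS}
    missing = set()
    for i, row in enumerate(nuclei[["slide_id", "region"]].itertuples(index=False)):
        for ch in CHANNELS:
            key = (row.slide_id, row.region, ch)
            if key not in lut:
                missing.add(key)
            else:
                thr[ch][i] = lut[key]
    if missing:
        raise ThresholdError(
            "no threshold for slide/region/channel group(s): "
            + ", ".join(map(str, sorted(missing)))
        )
    return thr["e1"], thr["e2"]


def filter_glia(
    nuclei: pd.DataFrame,
    thresholds: pd.DataFrame,
    size_quantile: float = 0.25,
    elongation_cut: float = 1.8,
    brightness_cut: float = 140.0,
) -> pd.DataFrame:
    """Label putative glial nuclei on morphology plus absent IEG signal.

    A nucleus is called ``putative_glia`` when all three hold: its size
    falls below the ``size_quantile`` of its slide's size distribution
    (glia are smaller), it is elongated (> ``elongation_cut``) or has a
    bright unstructured counterstain (> ``brightness_cut``), and both
    channel intensities are below their thresholds -- a nucleus with IEG
    signal is never excluded as glia.  Adds a ``cell_type`` column.
    """
    out = nuclei.copy()
    thr1, thr2 = _per_nucleus_thresholds(out, thresholds)
    small = np.zeros(len(out), dtype=bool)
    for slide, g in out.groupby("slide_id"):
        if len(g) < 10:
            warnings.warn(
                f"slide {slide}: only {len(g)} nuclei; size quantile is unstable"
            )
        cut = g["size"].quantile(size_quantile)
        small[out.index.get_indexer(g.index)] = g["size"].to_numpy() < cut
    shaped = (out["elongation"].to_numpy() > elongation_cut) | (
        out["counterstain_brightness"].to_numpy() > brightness_cut
    )
    no_signal = (out["intensity_e1_channel"].to_numpy() < thr1) & (
        out["intensity_e2_channel"].to_numpy() < thr2
    )
    out["cell_type"] = np.where(small & shaped & no_signal, "putative_glia", "neuron")
    return out


def classify_nuclei(nuclei: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Binary-threshold both channels and assign the four-way IEG class.

    Intensity exactly at threshold counts positive.  The green (Homer1a)
    channel reports epoch 1 / session A1 and the orange-red (Arc) channel
    epoch 2 / session A2.  The class is defined only for included
    neuronal nuclei; excluded rows keep ``iEG_class = NaN``.
    """
    out = nuclei.copy()
    if "included_mid_z" not in out.columns:
        out["included_mid_z"] = True
    if "cell_type" not in out.columns:
        out["cell_type"] = "neuron"
    thr1, thr2 = _per_nucleus_thresholds(out, thresholds)
    pos1 = out["intensity_e1_channel"].to_numpy(float) >= thr1
    pos2 = out["intensity_e2_channel"].to_numpy(float) >= thr2
    cls = np.select(
        [pos1 & pos2, pos1 & ~pos2, ~pos1 & pos2],
        ["double_pos", "homer_pos", "arc_pos"],
        default="negative",
    )
    out["included"] = out["included_mid_z"] & (out["cell_type"] == "neuron")
    out["iEG_class"] = pd.Series(cls, index=out.index).where(out["included"])
    return out


def region_proportions(classified: pd.DataFrame) -> pd.DataFrame:
    """Per animal x region counts and fractions of the four IEG classes.

    Also derives the per-epoch marginals ``p_e1 = p_homer_only + p_double``
    (session A1) and ``p_e2 = p_arc_only + p_double`` (session A2).
    Animal-regions with zero included nuclei yield a missing-value row
    with a warning rather than silently disappearing.
    """
    keys = ["animal_id", "treatment", "environment", "region"]
    rows = []
    for key_vals, g in classified.groupby(keys, sort=True):
        inc = g[g["included"]]
        n = len(inc)
        rec = dict(zip(keys, key_vals))
        rec["n_included"] = n
        if n == 0:
            warnings.warn(f"{key_vals}: zero included nuclei; proportions undefined")
            for c in IEG_CLASSES:
                rec[f"n_{c}"] = 0
                rec[f"p_{c}"] = np.nan
            rec["p_e1"] = rec["p_e2"] = np.nan
        else:
            counts = inc["iEG_class"].value_counts()
            for c in IEG_CLASSES:
                k = int(counts.get(c, 0))
                rec[f"n_{c}"] = k
                rec[f"p_{c}"] = k / n
            rec["p_e1"] = rec["p_homer_pos"] + rec["p_double_pos"]
            rec["p_e2"] = rec["p_arc_pos"] + rec["p_double_pos"]
        rows.append(rec)
    return pd.DataFrame(rows)


class NucleusClassifier(BaseEstimator):
    """Threshold-based four-way IEG nucleus classifier.

    ``fit`` derives the per slide x region x channel thresholds from the
    exemplar-flagged weakest positives (exploring animals only) and the
    per-slide size quantiles used by the glia rule; ``predict`` applies
    mid-Z selection, glia exclusion and binary thresholding, returning the
    classified table.  Follows the scikit-learn estimator protocol so the
    rule parameters are inspectable via ``get_params``.

    Parameters
    ----------
    band : float
        Mid-Z band width as a fraction of stack depth (default 0.20).
    threshold_stat : {"min", "quantile"}
        Statistic over exemplar intensities (default the minimum -- the
        exemplars are by construction the weakest genuine positives).
    threshold_quantile : float
        Quantile when ``threshold_stat="quantile"``.
    size_quantile, elongation_cut, brightness_cut : float
        Glia-rule cuts, see :func:`filter_glia`.
    """

    def __init__(
        self,
        band: float = 0.20,
        threshold_stat: str = "min",
        threshold_quantile: float = 0.0,
        size_quantile: float = 0.25,
        elongation_cut: float = 1.8,
        brightness_cut: float = 140.0,
    ):
        self.band = band
        self.threshold_stat = threshold_stat
        self.threshold_quantile = threshold_quantile
        self.size_quantile = size_quantile
        self.elongation_cut = elongation_cut
        self.brightness_cut = brightness_cut

    def fit(self, X: pd.DataFrame, y=None) -> "NucleusClassifier":
        missing = [c for c in REQUIRED_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"nuclei table missing columns {missing}")
        self.thresholds_ = derive_thresholds(
            X, statistic=self.threshold_stat, quantile=self.threshold_quantile
        )
        self.n_fit_ = len(X)
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("NucleusClassifier must be fitted before predict")
        staged = select_mid_z(X, band=self.band)
        staged = filter_glia(
            staged,
            self.thresholds_,
            size_quantile=self.size_quantile,
            elongation_cut=self.elongation_cut,
            brightness_cut=self.brightness_cut,
        )
        return classify_nuclei(staged, self.thresholds_)

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).predict(X)


def extract_features_from_stack(
    stack: np.ndarray,
    masks: np.ndarray,
    n_slices: Optional[int] = None,
    top_q: float = 0.01,
    meta: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-nucleus features from a 3-channel confocal stack + label masks.

    Parameters
    ----------
    stack : array, shape (z, 3, y, x)
        Channel 0 = nuclear counterstain, 1 = green (Homer1a / epoch 1),
        2 = orange-red (Arc / epoch 2).
    masks : integer array, shape (z, y, x)
        Nucleus label image; 0 is background.
    top_q : float
        The per-channel focus intensity is the mean of the brightest
        ``top_q`` fraction of in-mask voxels (at least one voxel), which
        captures bright intranuclear transcription foci rather than
        diffuse background.
    meta : dict, optional
        Identity columns (animal_id, treatment, environment, region,
        slide_id) to attach to every record.

    Elongation is the square root of the ratio of the largest to the
    smallest inertia-tensor eigenvalue of the mask (an aspect ratio).
    """
    from skimage import measure

    stack = np.asarray(stack)
    masks = np.asarray(masks)
    if stack.ndim != 4 or stack.shape[1] != 3:
        raise ValueError(f"stack must have shape (z, 3, y, x), got {stack.shape}")
    if masks.shape != (stack.shape[0], stack.shape[2], stack.shape[3]):
        raise ValueError(
            f"mask shape {masks.shape} does not match stack frames "
            f"{(stack.shape[0], stack.shape[2], stack.shape[3])}"
        )
    nz = n_slices or stack.shape[0]
    rows = []
    for prop in measure.regionprops(masks):
        coords = prop.coords  # (n_vox, 3) as (z, y, x)
        if coords.shape[0] == 0:
            warnings.warn(f"label {prop.label}: empty mask, skipped")
            continue
        zc = (prop.centroid[0] + 0.5) / nz
        eig = np.asarray(prop.inertia_tensor_eigvals, float)
        eig = np.clip(eig, 1e-12, None)
        elong = float(np.sqrt(eig.max() / eig.min()))

        def focus(ch: int) -> float:
            vals = stack[coords[:, 0], ch, coords[:, 1], coords[:, 2]].astype(float)
            k = max(1, int(np.ceil(top_q * vals.size)))
            return float(np.sort(vals)[-k:].mean())

        rec = dict(meta or {})
        rec.update(
            {
                "label": int(prop.label),
                "z_centroid_fraction": float(zc),
                "size": float(prop.area),
                "elongation": elong,
                "counterstain_brightness": float(
                    stack[coords[:, 0], 0, coords[:, 1], coords[:, 2]].mean()
                ),
                "intensity_e1_channel": focus(1),
                "intensity_e2_channel": focus(2),
            }
        )
        rows.append(rec)
    return pd.DataFrame(rows)
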