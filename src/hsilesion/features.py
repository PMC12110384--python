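"""Feature tables: one 93-feature radiomic vector per (lesion, region, channel).

Channels are the 12 tissue-index images plus "RGB" (the color photograph
reduced to Rec. 709 luminance).  Per-channel tables share the row order
(lesion x region); column names are ``<channel>|<CLASS>_<Feature>`` so the
pooled table has unique names with channel provenance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hsi_io import ReferenceFrames, SpectralCube, normalize_reflectance
from .indices import INDEX_SYMBOLS, TissueIndexStack, compute_all_indices
from .phantom import CLASS_LABELS, REGIONS, LesionRecord, StudyReplica
from .preprocess import mnf_denoise, render_rgb
from .radiomics import extract_features, luminance

__all__ = [
    "CHANNELS",
    "stack_from_spectral",
    "extract_lesion_features",
    "build_feature_tables",
]

CHANNELS = tuple(INDEX_SYMBOLS) + ("RGB",)


def stack_from_spectral(
    cube: SpectralCube,
    refs: ReferenceFrames,
    skin_mask: np.ndarray,
    denoise: bool = True,
    mnf_components: int | str = "auto",
) -> TissueIndexStack:
    """Raw cube -> reflectance -> (MNF) -> index stack + rendered RGB."""
    refl = normalize_reflectance(cube, refs)
    if denoise:
        refl = mnf_denoise(refl, n_components=mnf_components)
    rgb = render_rgb(refl)
    return compute_all_indices(refl, skin_mask=skin_mask, rgb=rgb)


def _channel_images(stack: TissueIndexStack) -> dict[str, np.ndarray]:
    images = dict(stack.indices)
    if stack.rgb is not None:
        images["RGB"] = luminance(stack.rgb)
    return images


def extract_lesion_features(
    record: LesionRecord, n_bins: int = 32
) -> dict[tuple[str, str], dict[str, float]]:
    """All (region, channel) feature vectors for one lesion.

    Returns ``{(region, channel): {feature_name: value}}``.
    """
    stack = record.stack
    if stack is None:
        if record.cube is None:
            raise ValueError("lesion record has neither a stack nor a cube")
        stack = stack_from_spectral(record.cube, record.refs,
                                    record.masks.skin)
        record.stack = stack
    images = _channel_images(stack)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for region in REGIONS:
        mask = record.masks.region(region)
        if not mask.any():
            continue
        for channel, image in images.items():
            out[(region, channel)] = extract_features(image, mask,
                                                      n_bins=n_bins)
    return out


def build_feature_tables(
    replica: StudyReplica, n_bins: int = 32
) -> tuple[dict[str, pd.DataFrame], pd.Series, pd.Series]:
    """Per-channel feature tables for a study replica.

    Returns ``(per_channel_tables, class_labels, lesion_ids)``; rows are
    (lesion, region) samples in replica order, identical across channels.
    """
    rows_by_channel: dict[str, list[dict]] = {c: [] for c in CHANNELS}
    index: list[tuple[str, str]] = []
    labels: list[str] = []
    for record in replica.lesions:
        per_lesion = extract_lesion_features(record, n_bins=n_bins)
        for region in REGIONS:
            index.append((record.lesion_id, region))
            labels.append(CLASS_LABELS[region])
            for channel in CHANNELS:
                rows_by_channel[channel].append(per_lesion[(region, channel)])
    row_index = pd.MultiIndex.from_tuples(index, names=["lesion_id", "region"])
    tables = {}
    for channel, rows in rows_by_channel.items():
        df = pd.DataFrame(rows, index=row_index)
        df.columns = [f"{channel}|{c}" for c in df.columns]
        tables[channel] = df
    label_series = pd.Series(labels, index=row_index, name="class_label")
    lesion_series = pd.Series([i[0] for i in index], index=row_index,
                              name="lesion_id")
    return tables, label_series, lesion_series
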