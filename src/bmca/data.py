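"""Observation containers: per-sample multi-omics log-ratios with
missingness and clipping masks.

All observations are relative to a reference strain.  Protein and
metabolite observations are natural-log ratios; flux observations are
absolute rates (mmol gDCW^-1 h^-1) whose deviations are scaled by
|v*| when clipped, so a single dimensionless clip bound applies to all
three data kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ObservedSample", "clip_observations", "samples_to_frame", "frame_to_samples"]

#: default clip bound, natural-log units
DEFAULT_CLIP_BOUND = 2.0


@dataclass
class ObservedSample:
    """One sample (strain x replicate) of multi-omics observations.

    Vectors are indexed like the model (reactions for proteins/fluxes,
    internal metabolites for metabolites); missing entries are NaN with
    the mask False.  ``*_clip`` holds -1/0/+1 for low-clipped /
    unclipped / high-clipped entries; ``raw_*`` keep pre-clip values.
    """

    sample_id: str
    strain_id: str
    protein_log: np.ndarray
    protein_mask: np.ndarray
    metabolite_log: np.ndarray
    metabolite_mask: np.ndarray
    flux_obs: np.ndarray
    flux_mask: np.ndarray
    protein_clip: np.ndarray = field(default=None)  # type: ignore[assignment]
    metabolite_clip: np.ndarray = field(default=None)  # type: ignore[assignment]
    flux_clip: np.ndarray = field(default=None)  # type: ignore[assignment]
    raw_protein_log: np.ndarray | None = None
    raw_metabolite_log: np.ndarray | None = None
    raw_flux_obs: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("protein", "metabolite"):
            if getattr(self, f"{name}_clip") is None:
                setattr(self, f"{name}_clip",
                        np.zeros_like(getattr(self, f"{name}_log"), dtype=int))
        if self.flux_clip is None:
            self.flux_clip = np.zeros_like(self.flux_obs, dtype=int)
        if not (self.protein_mask.any() or self.metabolite_mask.any()
                or self.flux_mask.any()):
            raise ValueError(f"sample {self.sample_id!r} has no observed entries")


def clip_observations(
    samples: list[ObservedSample],
    bound: float = DEFAULT_CLIP_BOUND,
    *,
    v_star: np.ndarray | None = None,
) -> list[ObservedSample]:
    """Clip extreme observations to keep data near the lin-log validity
    region.

    Log-ratio entries (protein, metabolite) with |value| > bound are
    replaced by +-bound and flagged.  Flux entries are clipped on the
    scaled deviation (v - v*)/|v*| when ``v_star`` is given, i.e. to
    v* -+ bound |v*|.  Originals are retained on the ``raw_*`` fields.
    Idempotent at a fixed bound.
    """
    if bound <= 0:
        raise ValueError("clip bound must be positive")
    out = []
    for s in samples:
        p_raw = s.raw_protein_log if s.raw_protein_log is not None else s.protein_log
        m_raw = s.raw_metabolite_log if s.raw_metabolite_log is not None else s.metabolite_log
        f_raw = s.raw_flux_obs if s.raw_flux_obs is not None else s.flux_obs
        p = np.clip(p_raw, -bound, bound)
        p_clip = np.where(s.protein_mask,
                          np.sign(p_raw) * (np.abs(p_raw) > bound), 0).astype(int)
        m = np.clip(m_raw, -bound, bound)
        m_clip = np.where(s.metabolite_mask,
                          np.sign(m_raw) * (np.abs(m_raw) > bound), 0).astype(int)
        if v_star is not None:
            scale = np.abs(v_star)
            dev = (f_raw - v_star) / scale
            f = v_star + np.clip(dev, -bound, bound) * scale
            f_clip = np.where(s.flux_mask,
                              np.sign(dev) * (np.abs(dev) > bound), 0).astype(int)
        else:
            f, f_clip = f_raw, np.zeros_like(s.flux_clip)
        out.append(replace(
            s,
            protein_log=p, metabolite_log=m, flux_obs=f,
            protein_clip=p_clip, metabolite_clip=m_clip, flux_clip=f_clip,
            raw_protein_log=p_raw, raw_metabolite_log=m_raw, raw_flux_obs=f_raw,
        ))
    return out


def samples_to_frame(
    samples: list[ObservedSample],
    reaction_ids: list[str],
    internal_ids: list[str],
) -> pd.DataFrame:
    """Long-format table (sample, strain, kind, feature_id, value, clipped)."""
    rows = []
    for s in samples:
        for kind, vec, mask, clip, feats in (
            ("protein", s.protein_log, s.protein_mask, s.protein_clip, reaction_ids),
            ("metabolite", s.metabolite_log, s.metabolite_mask, s.metabolite_clip, internal_ids),
            ("flux", s.flux_obs, s.flux_mask, s.flux_clip, reaction_ids),
        ):
            for i, fid in enumerate(feats):
                if mask[i]:
                    rows.append((s.sample_id, s.strain_id, kind, fid,
                                 float(vec[i]), int(clip[i])))
    return pd.DataFrame(rows, columns=["sample", "strain", "kind",
                                       "feature_id", "value", "clipped"])


def frame_to_samples(
    frame: pd.DataFrame,
    reaction_ids: list[str],
    internal_ids: list[str],
) -> list[ObservedSample]:
    """Inverse of :func:`samples_to_frame`."""
    ridx = {r: i for i, r in enumerate(reaction_ids)}
    midx = {m: i for i, m in enumerate(internal_ids)}
    nr, nm = len(reaction_ids), len(internal_ids)
    samples = []
    for (sid, strain), grp in frame.groupby(["sample", "strain"], sort=True):
        arrs = {
            "protein": (np.full(nr, np.nan), np.zeros(nr, bool), np.zeros(nr, int), ridx),
            "metabolite": (np.full(nm, np.nan), np.zeros(nm, bool), np.zeros(nm, int), midx),
            "flux": (np.full(nr, np.nan), np.zeros(nr, bool), np.zeros(nr, int), ridx),
        }
        for _, row in grp.iterrows():
            vec, mask, clip, idx = arrs[row["kind"]]
            i = idx[row["feature_id"]]
            vec[i] = row["value"]
            mask[i] = True
            clip[i] = int(row.get("clipped", 0))
        samples.append(ObservedSample(
            sample_id=str(sid), strain_id=str(strain),
            protein_log=arrs["protein"][0], protein_mask=arrs["protein"][1],
            metabolite_log=arrs["metabolite"][0], metabolite_mask=arrs["metabolite"][1],
            flux_obs=arrs["flux"][0], flux_mask=arrs["flux"][1],
            protein_clip=arrs["protein"][2], metabolite_clip=arrs["metabolite"][2],
            flux_clip=arrs["flux"][2],
        ))
    return samples
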