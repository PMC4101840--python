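"""Packing-density predictors, z-normalization, and the per-site table.

The local packing density (LPD) of a site is its crowding in the folded
structure: the weighted contact number WCN_i = sum_j 1/d_ij^2 (the pfANM
site stiffness) or the contact number CN_i = #{j : d_ij <= R_cut} (the
ANM site stiffness).  After per-protein z-score normalization the
mutational stress of a site is *identical* to its packing density
(z(MLmS) = z(k_i) = z(LPD)), while the MSF flexibility is only
approximately its reciprocal — the central structural identity this
package exposes.

``build_site_table`` assembles, for a set of CA traces plus a table of
per-site evolutionary rates (e.g. Rate4Site output, consumed as given),
the joined per-site record used by the model-comparison layer, with the
supplementary-table schema: pdb, chain, site, zwr4s, zbfactor,
zmsf_pfanm, zmlms_pfanm, zmsf_anm, zmlms_anm.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .enm import (
    DEFAULT_RCUT,
    EnsembleParams,
    SiteVector,
    build_anm,
    build_hessian,
    build_pfanm,
    covariance_from_hessian,
    msf_from_covariance,
    site_stiffness,
)
from .stress import mlms_analytic
from .structure_io import CaTrace

logger = logging.getLogger(__name__)

__all__ = [
    "znorm",
    "wcn",
    "cn",
    "build_site_table",
    "load_site_table",
    "SITE_TABLE_COLUMNS",
]

SITE_TABLE_COLUMNS = [
    "pdb",
    "chain",
    "site",
    "zwr4s",
    "zbfactor",
    "zmsf_pfanm",
    "zmlms_pfanm",
    "zmsf_anm",
    "zmlms_anm",
]


def _zscores(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("z-normalization needs at least 2 values")
    mean = x.mean()
    sd = np.sqrt(np.mean(x**2) - mean**2)  # population SD
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant site property cannot be z-normalized")
    return (x - mean) / sd


def znorm(values: SiteVector) -> SiteVector:
    """Per-protein z-score normalization with the population SD.

    x~_i = (x_i - <x>) / sqrt(<x^2> - <x>^2); the output has mean 0 and
    population SD 1 exactly.  Affine-equivariant: znorm(a*x + b) equals
    sign(a) * znorm(x).
    """
    return SiteVector(
        protein_id=values.protein_id,
        values=_zscores(values.values),
        quantity=values.quantity,
        normalized=True,
    )


def wcn(trace: CaTrace) -> SiteVector:
    """Weighted contact number WCN_i = sum_{j != i} 1/d_ij^2.

    Numerically identical to the pfANM site stiffness.
    """
    d = trace.distance_matrix()
    with np.errstate(divide="ignore"):
        w = 1.0 / d**2
    np.fill_diagonal(w, 0.0)
    if not np.all(np.isfinite(w)):
        raise ValueError("coincident sites give an infinite contact weight")
    return SiteVector(protein_id=trace.protein_id, values=w.sum(axis=1), quantity="WCN")


def cn(trace: CaTrace, rcut: float = DEFAULT_RCUT) -> SiteVector:
    """Contact number CN_i = #{j != i : d_ij <= rcut} (boundary inclusive).

    Numerically identical to the ANM site stiffness at the same cutoff.
    """
    if not rcut > 0:
        raise ValueError("rcut must be > 0")
    d = trace.distance_matrix()
    counts = ((d <= rcut).sum(axis=1) - 1).astype(float)  # exclude self
    return SiteVector(protein_id=trace.protein_id, values=counts, quantity="CN")


def _predictors_for_trace(
    trace: CaTrace, rcut: float, params: EnsembleParams
) -> pd.DataFrame:
    """Raw per-site predictors for one protein (one row per site)."""
    out = pd.DataFrame(
        {
            "pdb": trace.protein_id,
            "chain": trace.chain_id,
            "site": list(trace.site_labels),
        }
    )
    for model, builder in (("pfanm", build_pfanm), ("anm", lambda t: build_anm(t, rcut))):
        network = builder(trace)
        k_i = site_stiffness(network)
        try:
            cov = covariance_from_hessian(build_hessian(network))
        except ValueError as exc:
            logger.warning(
                "%s/%s: %s model skipped (%s)", trace.protein_id, trace.chain_id,
                model, exc,
            )
            out[f"msf_{model}"] = np.nan
            out[f"mlms_{model}"] = np.nan
            continue
        out[f"msf_{model}"] = msf_from_covariance(
            cov, params, protein_id=trace.protein_id
        ).values
        out[f"mlms_{model}"] = mlms_analytic(k_i, params).values
    out["bfactor"] = trace.bfactors if trace.bfactors is not None else np.nan
    return out


def build_site_table(
    traces: Iterable[CaTrace],
    rates: pd.DataFrame,
    rcut: float = DEFAULT_RCUT,
    params: EnsembleParams | None = None,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Join per-site predictors with evolutionary rates, z-scored per protein.

    Parameters
    ----------
    traces : iterable of CaTrace
    rates : DataFrame with columns (pdb, chain, site, rate)
        Raw site-specific rates; sites referencing residues absent from the
        structure are dropped (logged with a summary count), never imputed.
    rcut : ANM cutoff in Angstrom.
    params : EnsembleParams
        Scale parameters; z-scoring makes them immaterial for the outputs.
    min_sites : minimum matched sites for a protein to be retained.

    Returns
    -------
    DataFrame in the supplementary schema (`SITE_TABLE_COLUMNS`); within
    each protein every z column has mean 0 and population SD 1.
    """
    params = params or EnsembleParams()
    required = {"pdb", "chain", "site", "rate"}
    if not required.issubset(rates.columns):
        raise ValueError(f"rates table must have columns {sorted(required)}")
    rates = rates.assign(site=rates["site"].astype(str))

    frames: list[pd.DataFrame] = []
    n_dropped = 0
    for trace in traces:
        pred = _predictors_for_trace(trace, rcut, params)
        prot_rates = rates[
            (rates["pdb"] == trace.protein_id) & (rates["chain"] == trace.chain_id)
        ]
        merged = pred.merge(prot_rates[["site", "rate"]], on="site", how="inner")
        n_dropped += len(prot_rates) - len(merged)
        if len(merged) < min_sites:
            logger.warning(
                "%s/%s: only %d matched sites (< %d); protein excluded",
                trace.protein_id, trace.chain_id, len(merged), min_sites,
            )
            continue
        row = {"pdb": merged["pdb"], "chain": merged["chain"], "site": merged["site"]}
        row["zwr4s"] = _zscores(merged["rate"].to_numpy())
        for raw, col in (
            ("bfactor", "zbfactor"),
            ("msf_pfanm", "zmsf_pfanm"),
            ("mlms_pfanm", "zmlms_pfanm"),
            ("msf_anm", "zmsf_anm"),
            ("mlms_anm", "zmlms_anm"),
        ):
            vals = merged[raw].to_numpy()
            if np.all(np.isnan(vals)):
                row[col] = np.full(len(merged), np.nan)
            elif raw == "bfactor" and np.nanstd(vals) == 0:
                # constant B-factors (common in computed structures) carry no
                # signal; the B-factor flexibility variant is unavailable
                logger.warning(
                    "%s/%s: constant B-factors; zbfactor unavailable",
                    trace.protein_id, trace.chain_id,
                )
                row[col] = np.full(len(merged), np.nan)
            else:
                row[col] = _zscores(vals)
        frames.append(pd.DataFrame(row))
    if n_dropped:
        logger.warning("dropped %d rate rows with no matching structure site", n_dropped)
    if not frames:
        raise ValueError("no protein yielded enough matched sites")
    table = pd.concat(frames, ignore_index=True)
    if table.duplicated(["pdb", "chain", "site"]).any():
        raise ValueError("duplicate (pdb, chain, site) keys in site table")
    return table


def load_site_table(path: str | Path) -> pd.DataFrame:
    """Load a TSV site table in the supplementary schema.

    Accepts files written by :func:`build_site_table` / the CLI (comment
    lines starting with '#' are skipped) or the published supplementary
    site table itself.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"site": str, "chain": str})
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns and c != "zbfactor"]
    if missing:
        raise ValueError(f"site table is missing required columns: {missing}")
    if "zbfactor" not in df.columns:
        df["zbfactor"] = np.nan
    return df[SITE_TABLE_COLUMNS]
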