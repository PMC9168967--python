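"""TMT reporter normalization, PSM aggregation and ratio computation.

Reporter intensities are first scaled by global per-channel factors derived
from the proteome run (so that scaled per-channel proteome totals are
equal), glycopeptides with fewer than five PSMs are dropped, per-channel
median intensities over PSMs give the glycopeptide abundance, and the four
between-group ratios follow the channel map 129C = HCC paracancer,
130C = ICC paracancer, 130N = HCC tumor, 131 = ICC tumor.  Normalized
glycosylation divides each glycopeptide ratio by its parent protein's
expression ratio, isolating glycosylation-level change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .identify import GlycopeptidePSM, ProteomePSM
from .spectra import STUDY_CHANNELS

GROUP_OF = {"129C": "HCCP", "130C": "ICCP", "130N": "HCC", "131": "ICC"}
CHANNEL_OF = {g: c for c, g in GROUP_OF.items()}
RATIOS = ("ICC_ICCP", "HCC_HCCP", "ICC_HCC", "ICCP_HCCP")
MIN_PSM = 5


class ScalingError(ValueError):
    pass


@dataclass
class ScalingFactors:
    factors: dict[str, float]

    def __getitem__(self, channel: str) -> float:
        return self.factors[channel]


def proteome_psm_table(psms: list[ProteomePSM]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scan_id": [p.scan_id for p in psms],
            "protein_id": [p.peptide.protein_id for p in psms],
            "peptide": [p.peptide.sequence for p in psms],
            **{
                ch: [p.reporters.get(ch) for p in psms]
                for ch in STUDY_CHANNELS
            },
        }
    )


def glyco_psm_table(psms: list[GlycopeptidePSM]) -> pd.DataFrame:
    """PSM table mirroring the logical content of a supplementary PSM list."""
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in psms],
            "protein_id": [p.peptide.protein_id for p in psms],
            "peptide": [p.peptide.sequence for p in psms],
            "site": [p.site for p in psms],
            "composition": [p.structure.composition.serialize() for p in psms],
            "structure": [p.structure.canonical for p in psms],
            "peptide_score": [p.peptide_score for p in psms],
            "glycan_score": [p.glycan_score for p in psms],
            **{
                ch: [p.reporters.get(ch) for p in psms]
                for ch in STUDY_CHANNELS
            },
        }
    )


def proteome_scaling_factors(psm_table: pd.DataFrame) -> ScalingFactors:
    """factor(c) = mean over channels of totals / total(c)."""
    totals = {ch: float(psm_table[ch].sum(skipna=True)) for ch in STUDY_CHANNELS}
    if any(t <= 0 or not np.isfinite(t) for t in totals.values()):
        raise ScalingError(f"non-positive channel total: {totals}")
    mean_total = float(np.mean(list(totals.values())))
    return ScalingFactors({ch: mean_total / totals[ch] for ch in STUDY_CHANNELS})


def apply_scaling(psm_table: pd.DataFrame, factors: ScalingFactors) -> pd.DataFrame:
    out = psm_table.copy()
    for ch in STUDY_CHANNELS:
        out[ch] = out[ch] * factors[ch]
    return out


def _ratios_from_medians(med: dict[str, float]) -> dict[str, float]:
    g = {GROUP_OF[ch]: med.get(ch) for ch in STUDY_CHANNELS}
    out = {}
    for name in RATIOS:
        a, b = name.split("_")
        out[name] = (
            g[a] / g[b] if g.get(a) is not None and g.get(b) not in (None, 0) else np.nan
        )
    return out


def aggregate_glycopeptides(
    scaled_psms: pd.DataFrame, min_psm: int = MIN_PSM
) -> pd.DataFrame:
    """Per-glycopeptide medians and ratios; keys with < min_psm PSMs dropped.

    A PSM missing a reporter channel is excluded from that channel's median
    rather than imputed as zero.
    """
    key = ["protein_id", "peptide", "site", "structure"]
    rows = []
    for keyvals, grp in scaled_psms.groupby(key, sort=True):
        if len(grp) < min_psm:
            continue
        med = {ch: float(grp[ch].median(skipna=True)) for ch in STUDY_CHANNELS}
        row = dict(zip(key, keyvals))
        row["composition"] = grp["composition"].iloc[0]
        row["psm_count"] = len(grp)
        row.update({f"median_{ch}": med[ch] for ch in STUDY_CHANNELS})
        row.update(_ratios_from_medians(med))
        rows.append(row)
    return pd.DataFrame(rows)


def protein_quant(scaled_proteome_psms: pd.DataFrame) -> pd.DataFrame:
    """Per-protein channel medians over peptide PSMs, plus the four ratios."""
    rows = []
    for prot, grp in scaled_proteome_psms.groupby("protein_id", sort=True):
        med = {ch: float(grp[ch].median(skipna=True)) for ch in STUDY_CHANNELS}
        row = {"protein_id": prot, "psm_count": len(grp)}
        row.update({f"median_{ch}": med[ch] for ch in STUDY_CHANNELS})
        row.update(_ratios_from_medians(med))
        rows.append(row)
    return pd.DataFrame(rows)


def normalized_glycosylation(
    glycopeptide_ratio: float, protein_ratio: float | None
) -> tuple[float, str]:
    """Glycopeptide ratio divided by the parent protein's expression ratio.

    When the protein was not quantified the glycopeptide ratio passes
    through with status ``"protein-unquantified"``.
    """
    if protein_ratio is None or (isinstance(protein_ratio, float) and np.isnan(protein_ratio)):
        return glycopeptide_ratio, "protein-unquantified"
    if protein_ratio <= 0:
        raise ValueError(f"protein ratio must be positive, got {protein_ratio}")
    return glycopeptide_ratio / protein_ratio, "ok"


def add_normalized_glycosylation(
    quant: pd.DataFrame, protein_ratios: pd.DataFrame
) -> pd.DataFrame:
    """Attach norm_<ratio> columns (glycopeptide ratio / protein ratio)."""
    prot = protein_ratios.set_index("protein_id")
    out = quant.copy()
    statuses = []
    for name in RATIOS:
        out[f"norm_{name}"] = np.nan
    for i, row in out.iterrows():
        pid = row["protein_id"]
        known = pid in prot.index
        status = "ok" if known else "protein-unquantified"
        for name in RATIOS:
            pr = float(prot.loc[pid, name]) if known else None
            val, st = normalized_glycosylation(row[name], pr)
            out.loc[i, f"norm_{name}"] = val
            if st != "ok":
                status = st
        statuses.append(status)
    out["protein_status"] = statuses
    return out
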