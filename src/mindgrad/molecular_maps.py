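"""Molecular annotation panels: map correlations and the E/I ratio.

An :class:`AnnotationPanel` bundles M regional annotation maps (receptor
and transporter density stand-ins) with excitatory/inhibitory/other class
labels.  ``panel_correlations`` relates a case--control t-map to each
annotation with spin-test significance and Bonferroni correction across
the panel; ``ei_ratio`` forms the per-region ratio of mean z-scored
excitatory density to mean z-scored inhibitory density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

from mindgrad.exceptions import DegenerateInputError
from mindgrad.spatial_nulls import SpinEnsemble, adjust_bonferroni, spin_correlation_test
from mindgrad.synthetic_data import Parcellation, generate_annotation_map

#: default synthetic panel mirrors the multiple-testing burden of a
#: 19-map receptor/transporter atlas: 8 excitatory, 7 inhibitory, 4 other.
DEFAULT_PANEL_SPLIT = {"excitatory": 8, "inhibitory": 7, "other": 4}


@dataclass
class AnnotationPanel:
    """Regions x maps annotation matrix with a class per map."""

    maps: pd.DataFrame  # regions x M, columns = map names
    class_of_map: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.class_of_map) - set(self.maps.columns)
        if unknown:
            raise ValueError(f"classes given for unknown maps: {sorted(unknown)}")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[1]

    def names_in_class(self, cls: str) -> list:
        return [m for m in self.maps.columns if self.class_of_map.get(m) == cls]


def build_synthetic_panel(
    parcellation: Parcellation,
    smoothness: float = 0.5,
    seed: int = 0,
    split: Dict[str, int] = None,
) -> AnnotationPanel:
    """Simulate an annotation panel of independent spatially smooth maps."""
    split = dict(DEFAULT_PANEL_SPLIT if split is None else split)
    maps = {}
    classes = {}
    offset = 0
    for cls, count in split.items():
        for j in range(count):
            name = f"{cls[:3]}_{j + 1}"
            maps[name] = generate_annotation_map(
                parcellation, smoothness, seed=seed + offset
            )
            classes[name] = cls
            offset += 1
    df = pd.DataFrame(maps, index=parcellation.region_ids)
    df.index.name = "region_id"
    return AnnotationPanel(maps=df, class_of_map=classes)


def panel_correlations(
    t_map: np.ndarray, panel: AnnotationPanel, ensemble: SpinEnsemble
) -> pd.DataFrame:
    """Correlate the t-map with every panel map.

    Returns a DataFrame (map, class, r, p_spin, p_bonferroni) with the
    Bonferroni family size equal to the number of maps in the panel.
    """
    rows = []
    for name in panel.maps.columns:
        r, p = spin_correlation_test(t_map, panel.maps[name].to_numpy(), ensemble)
        rows.append({"map": name, "class": panel.class_of_map.get(name, "other"),
                     "r": r, "p_spin": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = adjust_bonferroni(out["p_spin"].to_numpy(), panel.n_maps)
    return out


def ei_ratio(panel: AnnotationPanel, eps: float = 1e-6) -> pd.DataFrame:
    """Excitatory/inhibitory ratio map.

    Every map is z-scored across regions (population SD); E_i and I_i are
    the regional means of the excitatory and inhibitory z-scores and the
    ratio is E_i / I_i.  Regions with |I_i| < eps are flagged unstable
    rather than dropped.
    """
    exc = panel.names_in_class("excitatory")
    inh = panel.names_in_class("inhibitory")
    if not exc or not inh:
        raise ValueError("panel needs at least one excitatory and one inhibitory map")
    z = {}
    for name in exc + inh:
        v = panel.maps[name].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            raise DegenerateInputError(f"map {name!r} is constant; z-score undefined")
        z[name] = (v - v.mean()) / sd
    E = np.mean([z[m] for m in exc], axis=0)
    I = np.mean([z[m] for m in inh], axis=0)
    unstable = np.abs(I) < eps
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(unstable, np.nan, E / np.where(unstable, 1.0, I))
    return pd.DataFrame(
        {
            "region_id": panel.maps.index,
            "excitatory_z": E,
            "inhibitory_z": I,
            "ei_ratio": ratio,
            "unstable": unstable,
        }
    )
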