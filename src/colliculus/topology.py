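"""Fixed lateral kernels and basal Gaussian inter-area weight matrices.

Lateral (intra-area) synapses realize near excitation / far inhibition via a
Mexican-hat difference of Gaussians of the inter-neuron distance d = |i - j|
(linear distance on the -90..+90 deg azimuth segment, no wrap-around), with
the self-connection (d = 0) set to zero. They are fixed (not plastic).

Inter-area synapses W^{H,Q}_{ij} (from presynaptic neuron j in area Q to
postsynaptic neuron i in area H) start as Gaussians of the distance between
preferred positions and are subject to Hebbian training; the SC -> SG weight
vector starts uniform at 1.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    INTER_AREA,
    LATERAL,
    N,
    POSITIONS,
    SOURCES,
    W0_SG_SC,
    LateralKernelParams,
    LearningParams,
)

__all__ = [
    "build_lateral_kernel",
    "build_inter_area_matrix",
    "build_sg_weights",
    "SynapseSet",
]

# |i - j| distance matrix shared by all builders
_DIST = np.abs(POSITIONS[:, None] - POSITIONS[None, :]).astype(float)


def build_lateral_kernel(params: LateralKernelParams) -> np.ndarray:
    """181x181 difference-of-Gaussians kernel with zeroed diagonal."""
    k = params.l_ex0 * np.exp(-(_DIST**2) / (2 * params.sigma_ex**2)) - params.l_in0 * np.exp(
        -(_DIST**2) / (2 * params.sigma_in**2)
    )
    np.fill_diagonal(k, 0.0)
    return k


def build_inter_area_matrix(w0: float, sigma: float) -> np.ndarray:
    """181x181 Gaussian matrix W_ij = W0 exp(-(i-j)^2 / (2 sigma^2))."""
    if w0 < 0:
        raise ValueError("W0 must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return w0 * np.exp(-(_DIST**2) / (2 * sigma**2))


def build_sg_weights(w0: float = W0_SG_SC) -> np.ndarray:
    """Uniform SC -> SG weight vector (length 181), basal value 1.1."""
    return np.full(N, float(w0))


@dataclass
class SynapseSet:
    """All plastic and fixed connectivity of the network.

    Attributes
    ----------
    inter : dict[(target, source)] -> (181, 181) ndarray
        The 12 excitatory inter-area matrices (plastic).
    w_sg : (181,) ndarray
        SC -> SG weights (plastic, no normalization).
    lateral : dict[area] -> (181, 181) ndarray
        Fixed Mexican-hat kernels.
    """

    inter: dict[tuple[str, str], np.ndarray]
    w_sg: np.ndarray
    lateral: dict[str, np.ndarray] = field(
        default_factory=lambda: {a: build_lateral_kernel(p) for a, p in LATERAL.items()}
    )

    @classmethod
    def basal(cls) -> "SynapseSet":
        """Pre-training configuration (Gaussian inter-area, uniform SC->SG)."""
        inter = {
            conn: build_inter_area_matrix(w0, sigma) for conn, (w0, sigma) in INTER_AREA.items()
        }
        return cls(inter=inter, w_sg=build_sg_weights())

    def copy(self) -> "SynapseSet":
        return SynapseSet(
            inter={k: v.copy() for k, v in self.inter.items()},
            w_sg=self.w_sg.copy(),
            lateral=self.lateral,  # fixed, shared
        )

    def incoming_sums(self, area: str) -> np.ndarray:
        """Per-neuron total incoming inter-area weight for a target area."""
        total = np.zeros(N)
        for src in SOURCES[area]:
            total += self.inter[(area, src)].sum(axis=1)
        return total

    def wmax(self, learning: LearningParams = LearningParams()) -> dict[tuple[str, str], float]:
        """Saturation value per connection: 1.8x the basal central weight."""
        return {conn: learning.wmax_factor * w0 for conn, (w0, _) in INTER_AREA.items()}

    def wmax_sg(self, learning: LearningParams = LearningParams()) -> float:
        return learning.wmax_sg_factor * W0_SG_SC

    # -- snapshots ---------------------------------------------------------
    def save_npz(self, path) -> None:
        """Binary snapshot of all weights (one array per connection)."""
        arrays = {f"{h}__{q}": w for (h, q), w in self.inter.items()}
        arrays["SG__SC"] = self.w_sg
        np.savez_compressed(path, **arrays)

    @classmethod
    def load_npz(cls, path) -> "SynapseSet":
        data = np.load(path)
        inter = {}
        w_sg = None
        for key in data.files:
            h, q = key.split("__")
            if h == "SG":
                w_sg = data[key]
            else:
                inter[(h, q)] = data[key]
        return cls(inter=inter, w_sg=w_sg)

    def to_tables(self, out_dir) -> None:
        """Tabular text export (one CSV per connection: pre, post, weight)."""
        import pandas as pd
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pre, post = np.meshgrid(POSITIONS, POSITIONS)
        for (h, q), w in self.inter.items():
            df = pd.DataFrame(
                {"pre_deg": pre.ravel(), "post_deg": post.ravel(), "weight": w.ravel()}
            )
            df.to_csv(out / f"W_{h}_{q}.csv", index=False)
        pd.DataFrame({"pre_deg": POSITIONS, "weight": self.w_sg}).to_csv(
            out / "W_SG_SC.csv", index=False
        )
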