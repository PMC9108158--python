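"""Per-subject, per-state connectivity summaries.

Once every window carries a state label, each subject's state is summarised
by the element-wise mean of its windows (a mean Fisher-z connectivity
matrix), the global mean over distinct ROI pairs, and per-network means for
the four large-scale networks of the parcellation: default mode (DMN),
cognitive control (CCN), sensorimotor (SMN) and occipital-cerebellum (OCN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dfc import n_edges, reconstruct_matrix, vectorize_upper

__all__ = [
    "NETWORKS",
    "Parcellation",
    "default_parcellation",
    "subject_state_mean_fc",
    "occurrence_counts",
    "global_mean_fc",
    "network_mean_fc",
    "top_fraction_edges",
]

NETWORKS = ("DMN", "CCN", "SMN", "OCN")

# ROI counts per network for the default 160-region parcellation, following
# the usual grouping of the 160-sphere atlas into four systems: default mode
# (34), cognitive control = cingulo-opercular + fronto-parietal (53),
# sensorimotor (33), occipital + cerebellum (40).
_DEFAULT_NETWORK_SIZES = {"DMN": 34, "CCN": 53, "SMN": 33, "OCN": 40}


@dataclass
class Parcellation:
    """ROI ids plus one network label per ROI."""

    roi_ids: list[str]
    networks: list[str]
    coordinates: np.ndarray | None = None  # optional R x 3 MNI coordinates

    def __post_init__(self) -> None:
        if len(self.roi_ids) != len(self.networks):
            raise ValueError("roi_ids and networks must have equal length")
        unknown = set(self.networks) - set(NETWORKS)
        if unknown:
            raise ValueError(f"unknown network label(s): {sorted(unknown)}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def network_indices(self, network: str) -> np.ndarray:
        if network not in NETWORKS:
            raise ValueError(f"unknown network {network!r}")
        return np.flatnonzero(np.asarray(self.networks) == network)


def default_parcellation(n_rois: int = 160) -> Parcellation:
    """A four-network parcellation with atlas-proportioned block sizes.

    At 160 ROIs the blocks match the default atlas grouping exactly; at other
    sizes the same proportions are used (each network keeps at least two
    ROIs so within-network means are defined).
    """
    if n_rois < 8:
        raise ValueError("need at least 8 ROIs for four 2-ROI networks")
    total = sum(_DEFAULT_NETWORK_SIZES.values())
    sizes = {
        net: max(2, int(round(cnt * n_rois / total)))
        for net, cnt in _DEFAULT_NETWORK_SIZES.items()
    }
    # adjust the largest block so sizes sum exactly to n_rois
    diff = n_rois - sum(sizes.values())
    sizes["CCN"] += diff
    labels: list[str] = []
    for net in NETWORKS:
        labels.extend([net] * sizes[net])
    roi_ids = [f"roi_{i:03d}" for i in range(n_rois)]
    return Parcellation(roi_ids=roi_ids, networks=labels)


def subject_state_mean_fc(
    windowed_fc: np.ndarray, labels: np.ndarray, state: int, n_rois: int
) -> np.ndarray:
    """Mean connectivity matrix of one subject's windows in one state.

    Element-wise mean over the subject's windows labelled ``state``,
    reconstructed to a symmetric R x R matrix (unit diagonal).
    """
    windowed_fc = np.asarray(windowed_fc, dtype=float)
    labels = np.asarray(labels)
    mask = labels == state
    if not mask.any():
        raise ValueError(
            f"state {state} absent from this subject's windows; the subject "
            "should have been excluded upstream"
        )
    return reconstruct_matrix(windowed_fc[mask].mean(axis=0), n_rois)


def occurrence_counts(labels: np.ndarray, k: int) -> np.ndarray:
    """Number of windows spent in each state (length-k count vector)."""
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError("labels out of range for k states")
    return np.bincount(labels, minlength=k)


def global_mean_fc(mean_fc_matrix: np.ndarray) -> float:
    """Mean over distinct ROI pairs (strict upper triangle, diagonal excluded).

    The diagonal of a Fisher-z connectivity matrix is the clamped transform
    of r = 1 — an arbitrary large constant — so it is excluded.
    """
    return float(vectorize_upper(mean_fc_matrix).mean())


def network_mean_fc(
    mean_fc_matrix: np.ndarray,
    parcellation: Parcellation,
    network: str,
    mode: str = "within",
) -> float:
    """Mean connectivity of one network.

    ``mode="within"``: mean over ROI pairs with both endpoints in the
    network.  ``mode="to_all"``: mean over pairs with at least one endpoint
    in the network (the network's connectivity to the whole brain).
    """
    if mode not in ("within", "to_all"):
        raise ValueError("mode must be 'within' or 'to_all'")
    matrix = np.asarray(mean_fc_matrix, dtype=float)
    if matrix.shape != (parcellation.n_rois, parcellation.n_rois):
        raise ValueError("matrix shape does not match parcellation")
    members = parcellation.network_indices(network)
    if mode == "within" and members.size < 2:
        raise ValueError(f"network {network} has fewer than 2 ROIs")
    in_net = np.zeros(parcellation.n_rois, dtype=bool)
    in_net[members] = True
    iu, ju = np.triu_indices(parcellation.n_rois, k=1)
    if mode == "within":
        mask = in_net[iu] & in_net[ju]
    else:
        mask = in_net[iu] | in_net[ju]
    return float(matrix[iu[mask], ju[mask]].mean())


def top_fraction_edges(
    edge_vector: np.ndarray, fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and values of the strongest ``fraction`` of edges, descending.

    The count is ``round-half-up(fraction * E)`` — e.g. the top 5 per mille
    of 12,720 edges is 63.6 -> 64 edges.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    edge_vector = np.asarray(edge_vector, dtype=float)
    m = int(math.floor(fraction * edge_vector.size + 0.5))
    if m == 0:
        raise ValueError("fraction selects zero edges")
    order = np.argsort(edge_vector, kind="stable")[::-1][:m]
    return order, edge_vector[order]
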