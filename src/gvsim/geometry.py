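"""Canal-plane geometry: per-ear afferent modulation -> head-frame rotation signal.

A binaural bipolar mastoid montage stimulates the anterior, posterior, and
horizontal canals of one ear non-preferentially and equally.  Treating unit
depolarization of a canal's afferents as unit virtual rotation about that
canal's excitatory axis, the head-frame virtual angular-velocity signal for
one ear is

    alpha_xyz(t) = R_y @ inv(N) @ [1, 1, 1]^T * dFR(t)

where the rows of N are the unit normals of that ear's canal planes (signed
as excitatory rotation axes) and R_y is a 7 deg rotation about the interaural
axis aligning the anatomical (Reid's-plane) frame with the naso-occipital
head frame (x out the nose, y out the left ear, z up).  Left and right ear
contributions are then combined linearly.

Default canal-plane normals are the average-human values measured by
multiplanar CT reconstruction (Della Santina et al. 2005), re-signed per
canal so that each normal points along the rotation axis that excites the
canal (right-hand rule), and mirrored for the left labyrinth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .afferent import AfferentChannelResponse, TransferFunctionSpec, default_tf_bank

__all__ = [
    "CanalBasis",
    "HeadFrameSignal",
    "DEFAULT_CANAL_NORMALS_RIGHT",
    "default_canal_basis",
    "afferent_to_head_frame",
    "combine_ears",
    "net_gvs_direction",
]

#: Average-human canal-plane unit normals, right ear, rows = (anterior,
#: posterior, horizontal), columns = (x nose, y left ear, z up).  Signed as
#: excitatory rotation axes: the anterior canal is excited by nose-down pitch
#: plus ipsilateral-ear-down roll, the posterior canal by nose-up pitch plus
#: ipsilateral roll, the horizontal canal by yaw toward the same side.
DEFAULT_CANAL_NORMALS_RIGHT = np.array(
    [
        [0.58930, 0.78839, 0.17655],   # anterior
        [0.69432, -0.66693, 0.27042],  # posterior
        [-0.32269, 0.03837, -0.94531], # horizontal (excited by rightward yaw)
    ]
)

#: Mirror of an angular-velocity (axial) vector across the midsagittal plane.
_MIRROR_AXIAL = np.diag([-1.0, 1.0, -1.0])

DEFAULT_ALIGNMENT_DEG = 7.0


def _rotation_about_y(angle_deg: float) -> np.ndarray:
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass
class CanalBasis:
    """Left/right canal-plane excitatory bases and the anatomical alignment rotation."""

    n_right: np.ndarray
    n_left: np.ndarray
    alignment_deg: float = DEFAULT_ALIGNMENT_DEG
    r_y: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.n_right = np.asarray(self.n_right, dtype=float)
        self.n_left = np.asarray(self.n_left, dtype=float)
        for name, n in (("n_right", self.n_right), ("n_left", self.n_left)):
            if n.shape != (3, 3):
                raise ValueError(f"{name} must be 3x3 (rows anterior/posterior/horizontal)")
            norms = np.linalg.norm(n, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError(f"{name} rows must be unit vectors; got norms {norms}")
            if abs(np.linalg.det(n)) < 1e-8:
                raise ValueError(f"{name} is singular; canal normals must span 3D")
        self.r_y = _rotation_about_y(self.alignment_deg)

    def basis(self, ear: str) -> np.ndarray:
        if ear == "right":
            return self.n_right
        if ear == "left":
            return self.n_left
        raise ValueError(f"ear must be 'left' or 'right', got {ear!r}")

    def ear_vector(self, ear: str) -> np.ndarray:
        """Head-frame virtual rotation axis for unit, equal activation of one ear's canals."""
        n = self.basis(ear)
        return self.r_y @ np.linalg.solve(n, np.ones(3))


@dataclass
class HeadFrameSignal:
    """3D head-frame angular-velocity-equivalent signal over time.

    ``units`` declares whether samples are firing-rate equivalents (dspk/s)
    or calibrated angular velocity (deg/s); frame is the x-nose / y-left /
    z-up head frame throughout.
    """

    time: np.ndarray
    alpha: np.ndarray  # (n, 3)
    units: str = "dspk/s"
    frame: str = "xyz-head"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.time.size, 3):
            raise ValueError("alpha must have shape (n_samples, 3)")
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha contains non-finite samples")
        if self.frame != "xyz-head":
            raise ValueError("only the xyz-head frame is supported")


def default_canal_basis(alignment_deg: float = DEFAULT_ALIGNMENT_DEG) -> CanalBasis:
    """Average-human canal basis with excitatory-axis sign convention."""
    n_right = DEFAULT_CANAL_NORMALS_RIGHT / np.linalg.norm(DEFAULT_CANAL_NORMALS_RIGHT, axis=1, keepdims=True)
    n_left = n_right @ _MIRROR_AXIAL.T
    return CanalBasis(n_right=n_right, n_left=n_left, alignment_deg=alignment_deg)


def afferent_to_head_frame(response: AfferentChannelResponse, basis: CanalBasis) -> HeadFrameSignal:
    """Resolve one ear's scalar afferent modulation into the head frame.

    Equal activation of the three canals gives alpha(t) = R_y inv(N) 1 * dFR(t).
    """
    v = basis.ear_vector(response.ear)
    alpha = np.outer(response.delta_fr, v)
    return HeadFrameSignal(time=response.time, alpha=alpha, units="dspk/s")


def combine_ears(alpha_right: HeadFrameSignal, alpha_left: HeadFrameSignal, k_r: float = 0.5) -> HeadFrameSignal:
    """Linear combination of left/right contributions, K_L = 1 - K_R (default equal)."""
    if not 0.0 <= k_r <= 1.0:
        raise ValueError("k_r must lie in [0, 1]")
    if alpha_right.time.shape != alpha_left.time.shape or not np.allclose(
        alpha_right.time, alpha_left.time
    ):
        raise ValueError("left/right signals must share one time grid")
    if alpha_right.units != alpha_left.units:
        raise ValueError("left/right signals must share units")
    alpha = k_r * alpha_right.alpha + (1.0 - k_r) * alpha_left.alpha
    return HeadFrameSignal(time=alpha_right.time, alpha=alpha, units=alpha_right.units)


def net_gvs_direction(
    basis: CanalBasis | None = None,
    tf_bank: dict[tuple[str, str], TransferFunctionSpec] | None = None,
    channel: str = "irregular",
    k_r: float = 0.5,
) -> np.ndarray:
    """Unit head-frame vector of the steady net virtual rotation under +1 mA DC.

    Positive current is left cathode (depolarizing, DC gain of the cathodal
    branch) and right anode (hyperpolarizing, minus the anodal DC gain).
    """
    if basis is None:
        basis = default_canal_basis()
    if tf_bank is None:
        tf_bank = default_tf_bank()
    dc_cath = tf_bank[(channel, "cathodal")].dc_gain
    dc_anod = tf_bank[(channel, "anodal")].dc_gain
    vec = k_r * basis.ear_vector("right") * (-dc_anod) + (1.0 - k_r) * basis.ear_vector("left") * dc_cath
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        raise ValueError("net GVS vector has zero magnitude")
    return vec / norm
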