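"""End-to-end inverse-problem drivers.

Each run solves one problem: the network(s) are trained from scratch by
minimizing the physics losses on the given strain/boundary data, and
the converged dimensionless outputs are mapped back to physical
material-parameter volumes.

Isotropic mode: a single UNet maps the 6-channel strain volume to
(Lam, M, six stresses); after training, (Lam, M) are re-dimensionalized
with the problem's stress/strain scales and converted to (E, nu).

Transversely isotropic mode: a Parameter UNet maps the per-channel mean
of the normalized strain volumes from the three loadings to the five
local stiffness terms, and a single weight-shared Stress UNet maps each
loading's strains to that loading's stresses; the training loss is the
mean of the three per-loading totals, and the converged stiffness terms
are converted to engineering constants at the end.  All loadings share
one (stress, strain) scale pair so that a single dimensionless
stiffness field is consistent across loadings.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constitutive import (
    lame_to_engineering_arrays,
    ti_local_to_engineering_arrays,
)
from .fields import (
    BoundaryTractions,
    ScaleSet,
    VolumetricField,
    nondimensionalize,
)
from .losses import (
    AdaptiveWeights,
    LossBreakdown,
    TotalLossIso,
    TotalLossTI,
    update_adaptive_weights,
)
from .nn import Adam, UNet3D, UNetConfig

__all__ = ["InversionConfig", "InversionResult",
           "invert_isotropic", "invert_transversely_isotropic"]

#: reference protocol: full-width UNet trained for 40k epochs
REFERENCE_WIDTHS = (64, 128, 256)
REFERENCE_EPOCHS = 40_000

#: reduced preset for CPU-scale problems
DESK_WIDTHS = (16, 32, 64)


@dataclass(frozen=True)
class InversionConfig:
    mode: str = "isotropic"                  # or "transversely_isotropic"
    epochs: int = REFERENCE_EPOCHS
    learning_rate: float = 1e-3
    widths: tuple[int, int, int] = REFERENCE_WIDTHS
    seed: int = 0
    log_every: int = 100
    loss_csv: Optional[str] = None
    min_loadings: int = 2

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.mode not in ("isotropic", "transversely_isotropic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def desk(cls, mode: str = "isotropic", epochs: int = 2000, **kw):
        """Reduced-width preset sized for single-CPU runs."""
        return cls(mode=mode, epochs=epochs, widths=DESK_WIDTHS, **kw)

    def digest(self) -> str:
        """Short hash identifying the full configuration."""
        import hashlib
        import json

        payload = json.dumps(
            {k: getattr(self, k) for k in
             ("mode", "epochs", "learning_rate", "widths", "seed",
              "min_loadings")}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class InversionResult:
    params: dict[str, np.ndarray]            # physical-unit volumes
    stresses: list[np.ndarray]               # per loading, physical units
    history: list[dict]
    scales: ScaleSet
    config: InversionConfig
    dimensionless: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def final_loss(self) -> float:
        return self.history[-1]["total"]


class _HistoryLog:
    def __init__(self, path: Optional[str], fieldnames: Sequence[str]):
        self.rows: list[dict] = []
        self._writer = None
        self._fh = None
        if path:
            self._fh = open(path, "w", newline="")
            self._writer = csv.DictWriter(self._fh, fieldnames=fieldnames)
            self._writer.writeheader()

    def append(self, row: dict) -> None:
        self.rows.append(row)
        if self._writer:
            self._writer.writerow(row)

    def close(self) -> None:
        if self._fh:
            self._fh.close()


def _check_finite(loss: float, epoch: int) -> None:
    if not math.isfinite(loss):
        raise FloatingPointError(
            f"training diverged at epoch {epoch}: loss = {loss}; "
            "reduce the learning rate or rescale the inputs"
        )


def _mare(est: np.ndarray, truth: np.ndarray) -> float:
    return 100.0 * float(np.mean(np.abs(est - truth) / np.abs(truth)))


def invert_isotropic(strain: VolumetricField, bc: BoundaryTractions,
                     cfg: InversionConfig,
                     truth: Optional[dict] = None) -> InversionResult:
    """Recover (E, nu) volumes from one loading's strains and tractions."""
    if cfg.mode != "isotropic":
        raise ValueError("config mode must be 'isotropic'")
    scaled, scaled_bc, scales = nondimensionalize(strain, bc)
    total = TotalLossIso(scaled, scaled_bc)
    weights = AdaptiveWeights(strain.grid_shape)
    net = UNet3D(UNetConfig(in_channels=6, out_channels=8, widths=cfg.widths,
                            param_channels=2, seed=cfg.seed))
    opt = Adam(net.params(), lr=cfg.learning_rate)
    x = scaled.values.astype(np.float32)

    names = ["epoch", "constitutive", "equilibrium", "boundary", "total"]
    if truth is not None:
        names += [f"mare_{k}" for k in sorted(truth)]
    log = _HistoryLog(cfg.loss_csv, names)
    try:
        y = None
        for epoch in range(cfg.epochs):
            y = net.forward(x)
            bd, dout = total(y, weights)
            _check_finite(bd.total, epoch)
            net.zero_grad()
            net.backward(dout)
            opt.step()
            update_adaptive_weights(weights, cfg.learning_rate)
            if epoch % cfg.log_every == 0 or epoch == cfg.epochs - 1:
                row = {"epoch": epoch, "constitutive": bd.constitutive,
                       "equilibrium": bd.equilibrium, "boundary": bd.boundary,
                       "total": bd.total}
                if truth is not None:
                    est = _iso_params(y, scales)
                    for k in sorted(truth):
                        row[f"mare_{k}"] = _mare(est[k], truth[k])
                log.append(row)
    finally:
        log.close()

    y = net.forward(x)
    params = _iso_params(y, scales)
    sigma = np.asarray(y[2:8], dtype=np.float64) * scales.sigma_star
    return InversionResult(
        params=params, stresses=[sigma], history=log.rows, scales=scales,
        config=cfg,
        dimensionless={"Lam": np.asarray(y[0], dtype=np.float64),
                       "M": np.asarray(y[1], dtype=np.float64)},
    )


def _iso_params(y: np.ndarray, scales: ScaleSet) -> dict[str, np.ndarray]:
    lam = np.asarray(y[0], dtype=np.float64) * scales.stiffness_scale
    mu = np.asarray(y[1], dtype=np.float64) * scales.stiffness_scale
    E, nu = lame_to_engineering_arrays(lam, mu)
    return {"E": E, "nu": nu, "lam": lam, "mu": mu}


def invert_transversely_isotropic(
        strains: Sequence[VolumetricField], bcs: Sequence[BoundaryTractions],
        orientation: VolumetricField, cfg: InversionConfig,
        truth: Optional[dict] = None) -> InversionResult:
    """Recover the five TI engineering-constant volumes from the X/Y/Z
    compression loadings and the known fiber orientation."""
    if cfg.mode != "transversely_isotropic":
        raise ValueError("config mode must be 'transversely_isotropic'")
    if orientation is None:
        raise ValueError("TI inversion requires the fiber orientation field")
    n_load = len(strains)
    if n_load != len(bcs):
        raise ValueError("need one BC set per loading")

    # one shared scale pair across loadings keeps the dimensionless
    # stiffness field consistent
    eps_star = max(float(np.abs(s.values).max()) for s in strains)
    sigma_star = max(b.max_traction() for b in bcs)
    scales = ScaleSet(sigma_star, eps_star)
    scaled = [VolumetricField(s.values / eps_star, s.spacing, s.channel_names)
              for s in strains]
    scaled_bcs = [b.scaled(1.0 / sigma_star) for b in bcs]

    total = TotalLossTI(scaled, scaled_bcs, orientation,
                        min_loadings=cfg.min_loadings)
    weights = AdaptiveWeights(strains[0].grid_shape)
    param_net = UNet3D(UNetConfig(in_channels=6, out_channels=5,
                                  widths=cfg.widths, param_channels=5,
                                  seed=cfg.seed))
    stress_net = UNet3D(UNetConfig(in_channels=6, out_channels=6,
                                   widths=cfg.widths, param_channels=0,
                                   seed=cfg.seed + 1))
    opt = Adam(param_net.params() + stress_net.params(), lr=cfg.learning_rate)

    xs = [s.values.astype(np.float32) for s in scaled]
    x_mean = np.mean(xs, axis=0).astype(np.float32)
    inv = 1.0 / n_load
    grid_shape = strains[0].grid_shape

    names = ["epoch", "constitutive", "equilibrium", "boundary", "total"]
    if truth is not None:
        names += [f"mare_{k}" for k in sorted(truth)]
    log = _HistoryLog(cfg.loss_csv, names)
    try:
        for epoch in range(cfg.epochs):
            weights.zero_grad()
            param_net.zero_grad()
            stress_net.zero_grad()
            c_out = param_net.forward(x_mean)
            c_flat = c_out.reshape(5, -1).T.astype(np.float64)
            dc_total = np.zeros_like(c_flat)
            parts = []
            # the Stress UNet shares weights across loadings: run each
            # loading's forward and backward back-to-back so its layer
            # caches stay consistent while gradients accumulate
            for l in range(n_load):
                sig = stress_net.forward(xs[l])
                part, dc, dsig = total.per_loading(l, c_flat, sig, weights)
                parts.append(part)
                dc_total += inv * dc
                stress_net.backward(inv * dsig)
            bd = LossBreakdown(
                float(np.mean([p.constitutive for p in parts])),
                float(np.mean([p.equilibrium for p in parts])),
                float(np.mean([p.boundary for p in parts])),
                per_loading=parts,
            )
            _check_finite(bd.total, epoch)
            param_net.backward(dc_total.T.reshape((5,) + grid_shape))
            opt.step()
            weights.g_const *= inv
            for g in weights.g_face.values():
                g *= inv
            update_adaptive_weights(weights, cfg.learning_rate)
            if epoch % cfg.log_every == 0 or epoch == cfg.epochs - 1:
                row = {"epoch": epoch, "constitutive": bd.constitutive,
                       "equilibrium": bd.equilibrium, "boundary": bd.boundary,
                       "total": bd.total}
                if truth is not None:
                    est = _ti_params(param_net.forward(x_mean), scales)
                    for k in sorted(truth):
                        row[f"mare_{k}"] = _mare(est[k], truth[k])
                log.append(row)
    finally:
        log.close()

    c_out = param_net.forward(x_mean)
    params = _ti_params(c_out, scales)
    stresses = [np.asarray(stress_net.forward(x), dtype=np.float64)
                * scales.sigma_star for x in xs]
    dimless = {k: np.asarray(c_out[i], dtype=np.float64)
               for i, k in enumerate(("c11", "c12", "c22", "c23", "c44"))}
    return InversionResult(params=params, stresses=stresses, history=log.rows,
                           scales=scales, config=cfg, dimensionless=dimless)


def _ti_params(c_out: np.ndarray, scales: ScaleSet) -> dict[str, np.ndarray]:
    c = np.asarray(c_out, dtype=np.float64) * scales.stiffness_scale
    Exx, Eyy, nxy, nyz, Gxy, Gyz = ti_local_to_engineering_arrays(
        c[0], c[1], c[2], c[3], c[4])
    return {"Exx": Exx, "Eyy": Eyy, "nu_xy": nxy, "nu_yz": nyz,
            "Gxy": Gxy, "Gyz": Gyz,
            "c11": c[0], "c12": c[1], "c22": c[2], "c23": c[3], "c44": c[4]}
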