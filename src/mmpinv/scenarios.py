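"""Named simulation scenarios: domains, parameters and initial conditions.

Each builder returns a :class:`Scenario` bundling the box domain, the model
parameters (with the requested degradation pathway active) and closed-form
initial conditions.  The bundled scenarios reproduce the study set-ups:

* ``ellipse2d``    — 2d invasion from an elliptical tumour seed at the origin,
* ``ellipsoid3d``  — the 3d analogue (prolate ellipsoidal seed),
* ``patchy2d``     — elliptical seed in a matrix of low, spatially varying
  suitability (suitability dynamics on),
* ``strip2d``      — invasion from the left edge into a checkerboard of
  suitable and unsuitable matrix.

``case`` selects which MMP species degrade the ECM: ``"both"``,
``"bound_only"`` (mu_s = 0) or ``"soluble_only"`` (mu_b = 0; in the
suitability scenarios this case also freezes the suitability, delta_s = 0,
since bound enzymes are the only agents that modify it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .homogenize import DiffusivityLaw
from .invasion import ModelParams, SimState
from .mesh import NodalField, SimplicialMesh
from .unitcell import BoxDomainSpec, build_box_mesh

CASES = ("both", "bound_only", "soluble_only")

# cubic diffusivity laws fitted by the bundled homogenization studies,
# scaled by the reference soluble-MMP diffusivity (nondimensional)
DS1 = 1.29e-2
LAW_2D = DiffusivityLaw(0.25, 0.33, 0.42, DS1, 2)
LAW_3D = DiffusivityLaw(0.89, -2.35, 2.46, DS1, 3)


def table_params(dim: int = 2) -> ModelParams:
    """Default nondimensional parameter set of the study."""
    return ModelParams(kappa_s=4.0, kappa_b=5.0, mu_s=1.0, mu_b=1.0,
                       beta_s=0.1, beta_b=0.1, delta_s=1.0,
                       diffusivity=LAW_2D if dim == 2 else LAW_3D)


@dataclass
class Scenario:
    """Complete, mesh-independent description of one simulation."""

    name: str
    case: str
    box: BoxDomainSpec
    params: ModelParams
    phi0: Callable[[np.ndarray], np.ndarray]
    cs0: Callable[[np.ndarray], np.ndarray] = lambda x: np.zeros(len(x))
    b0: Callable[[np.ndarray], np.ndarray] = lambda x: np.zeros(len(x))
    s0: Callable[[np.ndarray], np.ndarray] = lambda x: np.zeros(len(x))
    tau: float = 1e-2
    T: float = 5.0
    snapshot_times: tuple = (1.0, 3.0, 5.0)

    def build_mesh(self) -> SimplicialMesh:
        return build_box_mesh(self.box)

    def initial_state(self, mesh: SimplicialMesh) -> SimState:
        """Lagrange interpolants of the initial data, with range checks."""
        fields = {}
        for name, fn in (("phi", self.phi0), ("cs", self.cs0),
                         ("b", self.b0), ("s", self.s0)):
            f = NodalField.from_function(mesh, fn)
            fields[name] = f
        for name, lo, hi in (("phi", 0.0, 1.0), ("cs", 0.0, np.inf),
                             ("b", 0.0, np.inf), ("s", 0.0, 1.0)):
            v = fields[name].values
            if v.min() < lo - 1e-12 or v.max() > hi + 1e-12:
                raise ValueError(f"initial {name} outside [{lo}, {hi}]")
        return SimState(0.0, fields["phi"], fields["cs"],
                        fields["b"], fields["s"])

    def config(self) -> dict:
        return {"name": self.name, "case": self.case, "tau": self.tau,
                "T": self.T, "mesh_size": self.box.mesh_size,
                "snapshot_times": list(self.snapshot_times)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.config(), fh, indent=1)


def _case_params(dim: int, case: str, suitability: bool) -> ModelParams:
    if case not in CASES:
        raise ValueError(f"case must be one of {CASES}")
    p = table_params(dim)
    if case == "bound_only":
        p = p.replace(mu_s=0.0)
    elif case == "soluble_only":
        p = p.replace(mu_b=0.0)
        if suitability:
            # bound MMPs neither degrade the matrix nor alter its
            # suitability in this case, so s stays frozen at s0
            p = p.replace(delta_s=0.0)
    return p.replace(suitability_on=suitability)


def _ellipse_phi0(x):
    return 1.0 - np.exp(-((4 * x[:, 0]) ** 2 + (8 * x[:, 1]) ** 2))


def ellipse2d(case: str = "both", mesh_size: float = 0.025) -> Scenario:
    """2d invasion from an elliptical seed: phi0 = 1 - exp(-(4 x1)^2 - (8 x2)^2)
    on [-1, 1]^2; all enzymes start at zero; homogeneous matrix."""
    return Scenario("ellipse2d", case,
                    BoxDomainSpec(2, (-1.0, -1.0), (1.0, 1.0), mesh_size),
                    _case_params(2, case, suitability=False),
                    phi0=_ellipse_phi0)


def ellipsoid3d(case: str = "both", mesh_size: float = 2.0 / 39) -> Scenario:
    """3d invasion from a prolate ellipsoidal seed on [-1, 1]^3."""
    def phi0(x):
        return 1.0 - np.exp(-((4 * x[:, 0]) ** 2 + (4 * x[:, 1]) ** 2
                              + (8 * x[:, 2]) ** 2))
    sc = Scenario("ellipsoid3d", case,
                  BoxDomainSpec(3, (-1.0,) * 3, (1.0,) * 3, mesh_size),
                  _case_params(3, case, suitability=False),
                  phi0=phi0, snapshot_times=(2.0, 4.0, 5.0))
    return sc


def patchy2d(case: str = "both", mesh_size: float = 0.025) -> Scenario:
    """Elliptical seed in a largely unsuitable matrix:
    s0 = 1 - 0.1 (cos(4 pi x1) cos(4 pi x2))^2, suitability dynamics on."""
    def s0(x):
        return 1.0 - 0.1 * (np.cos(4 * np.pi * x[:, 0])
                            * np.cos(4 * np.pi * x[:, 1])) ** 2
    return Scenario("patchy2d", case,
                    BoxDomainSpec(2, (-1.0, -1.0), (1.0, 1.0), mesh_size),
                    _case_params(2, case, suitability=True),
                    phi0=_ellipse_phi0, s0=s0)


def strip2d(case: str = "both", mesh_size: float = 0.025) -> Scenario:
    """Invasion from the left edge into checkerboard suitability:
    phi0 = 1 - exp(-4 (1 + x1)), s0 = (1 + cos(4 pi x1) cos(4 pi x2)) / 2."""
    def phi0(x):
        return 1.0 - np.exp(-4.0 * (1.0 + x[:, 0]))

    def s0(x):
        return 0.5 * (1.0 + np.cos(4 * np.pi * x[:, 0])
                      * np.cos(4 * np.pi * x[:, 1]))
    return Scenario("strip2d", case,
                    BoxDomainSpec(2, (-1.0, -1.0), (1.0, 1.0), mesh_size),
                    _case_params(2, case, suitability=True),
                    phi0=phi0, s0=s0)


BUILDERS = {"ellipse2d": ellipse2d, "ellipsoid3d": ellipsoid3d,
            "patchy2d": patchy2d, "strip2d": strip2d}


def get_scenario(spec: str, mesh_size: float | None = None) -> Scenario:
    """Resolve ``"name"`` or ``"name:case"`` to a scenario instance."""
    name, _, case = spec.partition(":")
    if name not in BUILDERS:
        raise KeyError(f"unknown scenario {name!r}; have {sorted(BUILDERS)}")
    kwargs = {"case": case or "both"}
    if mesh_size is not None:
        kwargs["mesh_size"] = mesh_size
    return BUILDERS[name](**kwargs)


def from_json(path) -> Scenario:
    """Rebuild a scenario from a config written by :meth:`Scenario.to_json`."""
    with open(path) as fh:
        cfg = json.load(fh)
    sc = get_scenario(f"{cfg['name']}:{cfg['case']}",
                      mesh_size=cfg.get("mesh_size"))
    sc.tau = cfg.get("tau", sc.tau)
    sc.T = cfg.get("T", sc.T)
    sc.snapshot_times = tuple(cfg.get("snapshot_times", sc.snapshot_times))
    return sc
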