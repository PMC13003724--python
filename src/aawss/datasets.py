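"""Packaged study inputs.

The mesh- and time-step-sensitivity study tuples (element counts and
cycle-mean TAWSS from the transient solves on each grid) and the 22-row
patient cohort table, as used by the verification and cohort analyses.
"""

from __future__ import annotations

from importlib import resources

from .gci import GciStudy, TimestepStudy

#: Fine/medium/coarse mesh studies (element counts in millions converted to
#: absolute counts; phi = cycle-mean TAWSS in Pa on the analyzed cycle) for
#: the three representative geometries: a typical fusiform case, the most
#: complex case, and a typical saccular case.
MESH_STUDIES: dict[str, GciStudy] = {
    "patient3": GciStudy(n_elements=(2.6893e6, 1.1046e6, 0.4501e6),
                         phi=(0.48797, 0.48954, 0.49145)),
    "patient4": GciStudy(n_elements=(3.9755e6, 1.6459e6, 0.6797e6),
                         phi=(0.60314, 0.60392, 0.60815)),
    "patient12": GciStudy(n_elements=(2.8772e6, 1.1984e6, 0.5018e6),
                          phi=(0.85132, 0.85519, 0.86378)),
}

#: Time-step halving study on the medium mesh of the most complex geometry.
TIMESTEP_STUDY = TimestepStudy(dts=(0.01, 0.005, 0.0025),
                               phi=(0.60392, 0.60288, 0.60339))


def cohort_table_path():
    """Path to the packaged 22-patient cohort CSV."""
    return resources.files("aawss").joinpath("data/cohort_table.csv")
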