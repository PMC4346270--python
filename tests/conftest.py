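import numpy as np
import pytest

from memlip.synth import SynthParams, SiteParams, generate


def gro_line(resid, resname, name, atomid, x, y, z):
    return "%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n" % (resid, resname, name, atomid, x, y, z)


TOY_ANNOTATION = """residue_name,bead_name,species,roles,vdw_radius_A
ALA,BB,PROTEIN,BACKBONE_CA,2.3
POPE,PO4,POPE,HEADGROUP,2.3
POPE,C1,POPE,TAIL,2.3
CL,PO41,CL,HEADGROUP,2.3
CL,PO42,CL,HEADGROUP,2.3
"""


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory):
    """6-bead toy: 2 protein CA residues, 1 POPE (headgroup + tail), 1 CL
    with a two-bead headgroup pair."""
    d = tmp_path_factory.mktemp("toy")
    gro = d / "toy.gro"
    lines = ["toy system\n", "    6\n"]
    lines.append(gro_line(1, "ALA", "BB", 1, 1.000, 1.000, 1.200))
    lines.append(gro_line(2, "ALA", "BB", 2, 1.500, 1.000, 1.200))
    lines.append(gro_line(3, "POPE", "PO4", 3, 0.500, 0.500, 2.000))
    lines.append(gro_line(3, "POPE", "C1", 4, 0.500, 0.500, 1.700))
    lines.append(gro_line(4, "CL", "PO41", 5, 2.500, 2.500, 0.400))
    lines.append(gro_line(4, "CL", "PO42", 6, 2.600, 2.500, 0.400))
    lines.append("%10.5f%10.5f%10.5f\n" % (3.0, 3.0, 3.0))
    gro.write_text("".join(lines))
    ann = d / "annotation.csv"
    ann.write_text(TOY_ANNOTATION)
    return gro, ann


@pytest.fixture(scope="session")
def default_run():
    """Small default-composition synthetic run shared across tests."""
    params = SynthParams(n_steps=800, seed=7)
    return generate(params)


def recovery_params(seed, tau=30.0, n_steps=100_000, n_sites_per_leaflet=3,
                    n_cl=20, D=4.2e-6, capture_radius=0.1):
    """Dilute sharp-capture scenario for residence-time recovery.

    One CL-like species at low ambient density; capture is certain on zone
    entry (p_on = 1) and the binding pocket sits off the protein wall, so a
    released lipid almost always leaves the measurement zone in one step.
    Under these conditions species-level occupancy events coincide with
    single bound dwells and their mean recovers tau.
    """
    sites = []
    for k in range(n_sites_per_leaflet):
        for leaflet, phase in (("INNER", 0.0), ("OUTER", 0.5)):
            sites.append(SiteParams(
                f"{leaflet.lower()}{k}", leaflet,
                2 * np.pi * (k + phase) / n_sites_per_leaflet,
                capture_radius=capture_radius, tau={"CL": tau},
                p_on={"CL": 1.0}, anchor_half_separation=0.0,
                anchor_radial_offset=1.3))
    return SynthParams(box=(12.0, 12.0), protein_radius=1.8,
                       lipid_counts={"CL": (n_cl, n_cl)},
                       diffusion={"CL": D}, well=(0.0, 0.0, 0.0),
                       sites=tuple(sites), n_steps=n_steps, seed=seed)
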