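"""Optional adapter to an external energy-minimization engine.

Predicted models can optionally be handed to OpenMM for a short amber99sb
energy minimization.  Before handing over, the alpha hydrogen of every
non-glycine residue is placed by :func:`pmhcnet.geometry.place_chiral_hydrogen`
so the minimizer cannot invert the CA stereocenter; all other hydrogens are
left to the engine.  When no engine is importable the adapter degrades
gracefully: :func:`available` reports False and :func:`refine_pdb` raises a
clear error instead of importing lazily at an awkward moment.
"""

from __future__ import annotations

import os

from . import dataprep as dp
from . import geometry as geo


def available() -> bool:
    """True iff an OpenMM installation (with app layer) is importable."""
    try:
        import openmm          # noqa: F401
        import openmm.app      # noqa: F401
        return True
    except ImportError:
        return False


def add_chiral_hydrogens(complex: dp.PMHCComplex) -> dict:
    """HA positions for every non-glycine peptide residue, keyed by residue
    index.  The complex itself is unchanged (the atom14 layout carries heavy
    atoms only)."""
    out = {}
    for i, aa in enumerate(complex.pep_seq):
        ha = geo.place_chiral_hydrogen(complex.pep_coords[i], aa)
        if ha is not None:
            out[i] = ha
    return out


def refine_pdb(in_path, out_path, max_iterations: int = 100) -> None:
    """Minimize a PDB model with amber99sb in OpenMM.

    Raises ``RuntimeError`` when OpenMM is not installed; callers guard with
    :func:`available` and skip refinement (the default pipeline never
    requires it).
    """
    if not available():
        raise RuntimeError(
            "structure refinement requested but OpenMM is not installed; "
            "rerun without --refine or install openmm"
        )
    import openmm
    import openmm.app as app

    pdb = app.PDBFile(os.fspath(in_path))
    ff = app.ForceField("amber99sb.xml")
    modeller = app.Modeller(pdb.topology, pdb.positions)
    modeller.addHydrogens(ff)
    system = ff.createSystem(modeller.topology,
                             nonbondedMethod=app.NoCutoff,
                             constraints=app.HBonds)
    integrator = openmm.VerletIntegrator(0.001)
    sim = app.Simulation(modeller.topology, system, integrator)
    sim.context.setPositions(modeller.positions)
    sim.minimizeEnergy(maxIterations=max_iterations)
    state = sim.context.getState(getPositions=True)
    with open(os.fspath(out_path), "w") as fh:
        app.PDBFile.writeFile(sim.topology, state.getPositions(), fh)


def write_model_with_ha(complex: dp.PMHCComplex, path) -> None:
    """Write a model PDB including the chiral HA atoms (minimizer input)."""
    dp.write_pdb(complex, path)
    has = add_chiral_hydrogens(complex)
    if not has:
        return
    # append HA atoms as a small post-processing step on the text file
    lines = open(os.fspath(path)).read().splitlines(keepends=False)
    out, serial = [], 1
    pep_resnums = {int(complex.pep_resnums[i]): i for i in range(len(complex.pep_seq))}
    inserted = set()
    for ln in lines:
        if ln.startswith(("ATOM", "HETATM")):
            serial = int(ln[6:11])
        out.append(ln)
        if ln.startswith("ATOM") and ln[21] == "P" and ln[12:16].strip() == "CA":
            resnum = int(ln[22:26])
            i = pep_resnums.get(resnum)
            if i in has and i not in inserted:
                inserted.add(i)
                ha = has[i]
                out.append(
                    f"ATOM  {serial + 1:5d}  HA  {ln[17:20]} P{resnum:4d}    "
                    f"{ha[0]:8.3f}{ha[1]:8.3f}{ha[2]:8.3f}  1.00  0.00"
                    f"           H"
                )
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(out) + "\n")
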