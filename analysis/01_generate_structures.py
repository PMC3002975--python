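#!/usr/bin/env python
"""Generate the model structures analysed downstream.

Close-packed systems whose contact networks we study:
  * the 500-site HCP reference cluster (stacked hexagonal plates) and
    300-site radial-fill clusters of all four lattices;
  * a jittered HCP cluster as a loose stand-in for the disorder of an
    energy-minimized Lennard-Jones cluster;
  * a dense hard-sphere packing standing in for a micelle core;
  * a self-avoiding chain packing standing in for a compressed melt.

Writes extended-XYZ files plus a run manifest per structure under
results/structures/.
"""

from pathlib import Path

from packnet.io import write_manifest, write_xyz
from packnet.structure_generators import (LatticeSpec,
                                          generate_hard_sphere_packing,
                                          generate_lattice_cluster,
                                          generate_polymer_melt_proxy)

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "results" / "structures"


def save(coords, name, params):
    OUT.mkdir(parents=True, exist_ok=True)
    write_xyz(coords, OUT / f"{name}.xyz", comment=name)
    write_manifest(params, OUT / f"{name}.manifest")
    print(f"  {name}: {coords.n_points} sites")


def main():
    print("generating lattice clusters")
    hcp = LatticeSpec(lattice_type="HCP", n_sites=500, fill_rule="hex_plate")
    save(generate_lattice_cluster(hcp), "hcp500",
         {"lattice": "HCP", "n_sites": 500, "fill_rule": "hex_plate"})
    for lat in ("HCP", "FCC", "BCC", "SC"):
        spec = LatticeSpec(lattice_type=lat, n_sites=300)
        save(generate_lattice_cluster(spec), f"{lat.lower()}300",
             {"lattice": lat, "n_sites": 300, "fill_rule": "radial"})

    print("generating disordered stand-ins")
    ljc = LatticeSpec(lattice_type="HCP", n_sites=500, fill_rule="radial",
                      jitter_sigma=0.05, seed=SEED)
    save(generate_lattice_cluster(ljc), "ljc_proxy500",
         {"lattice": "HCP", "n_sites": 500, "jitter_sigma": 0.05,
          "seed": SEED})

    micelle = generate_hard_sphere_packing(300, 1.0, 5.0, seed=SEED)
    save(micelle, "micelle_proxy300",
         {"n_points": 300, "min_dist": 1.0, "container_radius": 5.0,
          "seed": SEED})

    melt = generate_polymer_melt_proxy(n_chains=12, chain_length=25,
                                       bond_length=1.0, min_dist=1.0,
                                       container_radius=5.5, seed=SEED)
    save(melt, "melt_proxy300",
         {"n_chains": 12, "chain_length": 25, "bond_length": 1.0,
          "min_dist": 1.0, "container_radius": 5.5, "seed": SEED})


if __name__ == "__main__":
    main()
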