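"""Build the idealized ventricular and atrial meshes and inspect them.

Generates the default two-chamber ventricular mesh (truncated prolate
ellipsoids with analytic universal coordinates and rule-based fibers)
and the two-shell atrial mesh with its tagged anatomical structures,
then prints their composition and writes VTK files for viewing.
"""

import numpy as np

from ecgforge import build_atrial_mesh, build_ventricular_mesh, write_vtk

vent = build_ventricular_mesh()
print(f"ventricles: {vent.n_nodes} nodes, {vent.n_elements} hexahedra "
      f"at {vent.resolution} mm")
for tag, count in zip(*np.unique(vent.element_region, return_counts=True)):
    print(f"  {tag:<22s} {count:>6d} elements")
print(f"  LV long axis {vent.metadata['lv_long_axis']:.1f} mm, "
      f"apico-basal arcs {vent.metadata['arc_length']['lv']:.0f} / "
      f"{vent.metadata['arc_length']['rv']:.0f} mm (LV/RV)")

atria = build_atrial_mesh()
print(f"\natria: {atria.n_nodes} nodes, {atria.n_elements} hexahedra")
for tag, count in zip(*np.unique(atria.element_region, return_counts=True)):
    print(f"  {tag:<22s} {count:>6d} elements")
sa = atria.metadata["sa_node_nodes"]
print(f"  sinoatrial exit site: {len(sa)} nodes at the crista "
      "terminalis / SVC junction")

write_vtk(vent, "ventricles.vtk", point_data={"rho": vent.uvc["rho"],
                                              "z": vent.uvc["z"]})
write_vtk(atria, "atria.vtk")
print("\nwrote ventricles.vtk and atria.vtk (legacy ASCII, e.g. for "
      "ParaView)")
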