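# biofilmquant

Quantification of biofilm architecture on corroding concrete from
multi-channel confocal (CLSM) z-stacks and 3D excitation–emission matrices
(EEM).

Biofilms driving microbially induced concrete corrosion are a matrix of
extracellular polymeric substances (EPS — proteins, polysaccharides, nucleic
acids, lipids) embedding live and dead bacteria. A five-fluorophore staining
scheme (FITC → protein, Calcofluor White → polysaccharide, Nile Red → lipid,
rhodamine → all bacteria, propidium iodide → dead bacteria) turns a confocal
z-stack into per-component 3D occupancy maps. This package implements the
desk side of such a study for microbiologists and materials scientists who
have the stacks but not the proprietary modeling software:

* stack I/O (OME-TIFF) with voxel-size metadata, mask and mesh export;
* illumination ("shadow") correction, grayscale conversion, denoising;
* per-channel threshold segmentation and component assignment under the
  multi-stain scheme, with fluorophore cross-talk checking;
* fluorescent volume extraction and the EPS mass budget

  ```
  EPS_I  = m · V_I / V          (mass of one EPS component)
  EPS_II = m · (V − V_B) / V    (total EPS mass, cells excluded)
  ```

  where `m` is the measured biofilm mass (mg), `V` the total biofilm
  volume, `V_I` the fluorescent volume of one component and `V_B` the
  bacterial volume (all µm³);
* depth-resolved composition profiles and k-means layer clustering;
* representative elementary volume (REV) analysis of volume-fraction
  stability versus subvolume size;
* iso-surface mesh export (STL/OBJ/PLY) with enclosed-volume computation;
* EEM parsing, Rayleigh-scatter masking, peak detection and classification
  into the protein-like regions Peak A (Ex 275–280 / Em 325–350 nm,
  tryptophan-like) and Peak B (Ex 225 / Em 300 nm, tyrosine-like), with
  between-condition intensity-ratio reports;
* a ground-truthed synthetic data generator emulating the low-salinity
  (FQHC) and high-salinity (SQHC) regimes, so the whole pipeline is testable
  without any acquisition.

## Worked example

Generate a high-salinity synthetic field with known ground truth, segment
it, and compute the mass budget for a 5 mg biofilm sample:

```python
from biofilmquant import (
    assign_components, biofilm_quant, depth_profile, generate_stack,
    preset_recipe, table1_channel_map,
)

stack, truth = generate_stack(preset_recipe("SQHC", seed=7))
cmap = table1_channel_map(include_nucleic_acid=True)
masks = assign_components(stack, cmap)
quant = biofilm_quant(masks, stack.voxel_size, m_mg=5.0)

print(f"total biofilm volume V = {quant.V:.0f} um^3")
for comp, v in quant.V_I.items():
    print(f"{comp:14s} V_I = {v:7.0f} um^3   EPS_I = {quant.EPS_I[comp]:.3f} mg")
print(f"bacteria volume V_B = {quant.V_B:.0f} um^3")
print(f"total EPS mass EPS_II = {quant.EPS_II:.3f} mg")

prof = depth_profile(masks, stack.voxel_size, 10.0, normalize="within_component")
for comp in ("all_bacteria", "nucleic_acid"):
    b = prof.component_mode_bin(comp)
    print(f"{comp} is enriched at {prof.bin_edges[b]:.0f}-{prof.bin_edges[b+1]:.0f} um depth")
```

Output:

```
total biofilm volume V = 75129 um^3
protein        V_I =   15637 um^3   EPS_I = 1.041 mg
polysaccharide V_I =   15376 um^3   EPS_I = 1.023 mg
nucleic_acid   V_I =   13405 um^3   EPS_I = 0.892 mg
lipid          V_I =   10594 um^3   EPS_I = 0.705 mg
bacteria volume V_B = 21048 um^3
total EPS mass EPS_II = 3.599 mg
all_bacteria is enriched at 10-20 um depth
nucleic_acid is enriched at 30-40 um depth
```

The volumes are voxel counts times voxel volume; the masses follow the two
formulas above exactly; the depth modes reproduce the high-salinity
stratification the generator encodes (bacteria in the 10–20 µm surface
layer, extracellular DNA at 30–40 µm).

The same pipeline is available from the shell:

```bash
biofilmquant fixtures --out demo --seed 7     # synthetic stack + truth + EEM pair
biofilmquant quantify demo/run_config.yaml    # masks, CSVs, meshes, manifest
biofilmquant eem demo/eem_reference.csv demo/eem_test.csv --output demo/eem
```

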