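# Demo run: synthesize a six-helix pore trajectory with a 15-degree imposed
# helix rotation plus thermal noise, then recover the rotation and the water
# occupancy profile.  Run with:  poregate run examples/demo_pipeline.yaml
outdir: scratch/demo_run
seed: 1
stages:
  - name: reference
    kind: build_pore
    params: {}
  - name: trajectory
    kind: trajectory
    params:
      pore: {}
      n_frames: 60
      rotation_offsets: 15.0
      coordinate_noise_sd: 0.3
      water_axial_density:
        z_edges: [-20.0, 20.0]
        lam: [2.0]
  - name: rotation
    kind: rotation
    needs: [trajectory, reference]
    params:
      trajectory: trajectory
      reference: reference
      residue: 171
  - name: occupancy
    kind: occupancy
    needs: [trajectory]
    params:
      trajectories: trajectory
      species: water
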