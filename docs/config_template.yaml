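# myoquant configuration template.
# Any section may be omitted; omitted keys take the defaults shown here.
# Lengths are in pixels, areas in px^2, intensities in arbitrary units
# on the 16-bit scale of the simulated/recorded TIFFs.

# Which channel index holds which stain in the input TIFFs.
channel_roles:
  nuclei: 0        # DAPI
  myotubes: 1      # MF20 (myosin heavy chain)

# Parameters of the segmentation + quantification pipeline.
pipeline:
  blur_sigma_px: 1.0              # Gaussian smoothing of both channels
  nucleus_connectivity: 8         # 4 or 8, for nucleus particle analysis
  nucleus_min_area_px: 40         # junk filter: smaller objects dropped
  nucleus_max_area_px: 2000       # larger objects (clumps, debris) dropped
  nucleus_seed_separation_px: 6   # ~expected nucleus radius
  myotube_dilate_iters: 4         # the canonical 4x dilate
  myotube_erode_iters: 3          # ... and 3x erode (net +1 growth kept)
  myotube_min_area_px: 500        # minimum myotube ROI area
  myotube_seed_separation_px: 15  # ~myotube half-width
  mfi_min_nuclei: 2               # nuclei needed to count an object as fused
  histogram_bins: [1, 2, 5]       # left edges: bins 1, 2-4, >=5

# Parameters of the synthetic micrograph generator (myoquant simulate).
simulation:
  height_px: 512
  width_px: 512
  n_nuclei: 150
  nucleus_radius_mean_px: 6.0
  nucleus_radius_sd_px: 0.8
  nucleus_eccentricity_max: 0.6   # in [0, 1)
  touching_pair_fraction: 0.2     # fraction of nuclei laid down as touching pairs
  n_myotubes: 6
  myotube_width_px: 30.0
  myotube_length_px: 300.0
  target_mdi: 0.5                 # desired fraction of nuclei inside myotubes
  # multinucleation_profile: [10, 8, 5, 3, 2, 1]   # optional per-tube counts
  psf_sigma_px: 1.0
  background_level: 100.0
  noise_sd: 25.0
  nucleus_intensity: 2500.0
  myotube_intensity: 1800.0
  seed: 0
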