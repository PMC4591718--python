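# Canonical ROI registry.
#
# Subcortical structures: the seven bilaterally segmented gray-matter nuclei
# produced by FreeSurfer's aseg volumetric segmentation.  `freesurfer` is the
# label stem in aseg.stats (prefixed with Left-/Right- per hemisphere).
#
# Cortical parcels: the 34 Desikan-Killiany surface parcels per hemisphere,
# ordered by lobe (temporal, frontal, parietal, occipital, cingulate, insula).
# `freesurfer` is the StructName in lh.aparc.stats / rh.aparc.stats.
#
# Atlas renames are edits to this file, not to code.

subcortical:
  - {name: thalamus,    freesurfer: Thalamus-Proper}
  - {name: caudate,     freesurfer: Caudate}
  - {name: putamen,     freesurfer: Putamen}
  - {name: pallidum,    freesurfer: Pallidum}
  - {name: hippocampus, freesurfer: Hippocampus}
  - {name: amygdala,    freesurfer: Amygdala}
  - {name: accumbens,   freesurfer: Accumbens-area}

cortical:
  - {name: entorhinal,                freesurfer: entorhinal,               lobe: temporal}
  - {name: parahippocampal,           freesurfer: parahippocampal,          lobe: temporal}
  - {name: temporal_pole,             freesurfer: temporalpole,             lobe: temporal}
  - {name: fusiform,                  freesurfer: fusiform,                 lobe: temporal}
  - {name: superior_temporal,         freesurfer: superiortemporal,         lobe: temporal}
  - {name: middle_temporal,           freesurfer: middletemporal,           lobe: temporal}
  - {name: inferior_temporal,         freesurfer: inferiortemporal,         lobe: temporal}
  - {name: transverse_temporal,       freesurfer: transversetemporal,       lobe: temporal}
  - {name: bankssts,                  freesurfer: bankssts,                 lobe: temporal}
  - {name: superior_frontal,          freesurfer: superiorfrontal,          lobe: frontal}
  - {name: caudal_middle_frontal,     freesurfer: caudalmiddlefrontal,      lobe: frontal}
  - {name: rostral_middle_frontal,    freesurfer: rostralmiddlefrontal,    lobe: frontal}
  - {name: pars_opercularis,          freesurfer: parsopercularis,          lobe: frontal}
  - {name: pars_orbitalis,            freesurfer: parsorbitalis,            lobe: frontal}
  - {name: pars_triangularis,         freesurfer: parstriangularis,        lobe: frontal}
  - {name: medial_orbitofrontal,      freesurfer: medialorbitofrontal,     lobe: frontal}
  - {name: lateral_orbitofrontal,     freesurfer: lateralorbitofrontal,    lobe: frontal}
  - {name: frontal_pole,              freesurfer: frontalpole,             lobe: frontal}
  - {name: paracentral,               freesurfer: paracentral,             lobe: frontal}
  - {name: precentral,                freesurfer: precentral,              lobe: frontal}
  - {name: postcentral,               freesurfer: postcentral,             lobe: parietal}
  - {name: supramarginal,             freesurfer: supramarginal,           lobe: parietal}
  - {name: superior_parietal,         freesurfer: superiorparietal,        lobe: parietal}
  - {name: inferior_parietal,         freesurfer: inferiorparietal,        lobe: parietal}
  - {name: precuneus,                 freesurfer: precuneus,               lobe: parietal}
  - {name: lingual,                   freesurfer: lingual,                 lobe: occipital}
  - {name: pericalcarine,             freesurfer: pericalcarine,           lobe: occipital}
  - {name: cuneus,                    freesurfer: cuneus,                  lobe: occipital}
  - {name: lateral_occipital,         freesurfer: lateraloccipital,        lobe: occipital}
  - {name: rostral_anterior_cingulate, freesurfer: rostralanteriorcingulate, lobe: cingulate}
  - {name: caudal_anterior_cingulate, freesurfer: caudalanteriorcingulate, lobe: cingulate}
  - {name: posterior_cingulate,       freesurfer: posteriorcingulate,      lobe: cingulate}
  - {name: isthmus_cingulate,         freesurfer: isthmuscingulate,        lobe: cingulate}
  - {name: insula,                    freesurfer: insula,                  lobe: insula}
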