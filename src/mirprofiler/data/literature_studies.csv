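study,n_samples,mirna,direction,fold_change
Chen,24,hsa-miR-21,up,
Iorio,110,hsa-miR-21,up,
Tahiri,58,hsa-miR-21,up,
Tanic,36,hsa-miR-21,up,
Yan,8,hsa-miR-21,up,
Iorio,110,hsa-miR-155,up,
Tahiri,58,hsa-miR-155,up,
Yan,8,hsa-miR-155,up,
Iorio,110,hsa-miR-210,up,1.43
Tahiri,58,hsa-miR-210,up,3.03
Iorio,110,hsa-miR-149,up,1.08
Tahiri,58,hsa-miR-149,up,2.8
Chen,24,hsa-miR-183,up,
Tahiri,58,hsa-miR-183,up,
Chen,24,hsa-miR-200b,up,
Tahiri,58,hsa-miR-200b,up,
Chen,24,hsa-miR-141,up,
Tahiri,58,hsa-miR-141,up,
Chen,24,hsa-miR-425,up,
Tahiri,58,hsa-miR-425,up,
Chen,24,hsa-miR-106b,up,
Tahiri,58,hsa-miR-106b,up,
Chen,24,hsa-miR-20a,up,
Tahiri,58,hsa-miR-20a,up,
Tahiri,58,hsa-miR-98,up,1.88
Yan,8,hsa-miR-98,up,2.13
Tahiri,58,hsa-miR-181b,up,
Yan,8,hsa-miR-181b,up,
Ouyang,6,hsa-miR-1280,up,
Tahiri,58,hsa-miR-1280,up,
Chen,24,hsa-let-7f,up,
Yan,8,hsa-let-7f,up,
Chen,24,hsa-miR-29b-3p,up,
Yan,8,hsa-miR-29b-3p,up,
Iorio,110,hsa-miR-145,down,
Tahiri,58,hsa-miR-145,down,
Tanic,36,hsa-miR-145,down,
Iorio,110,hsa-miR-143,down,
Tahiri,58,hsa-miR-143,down,
Tanic,36,hsa-miR-143,down,
Iorio,110,hsa-let-7d,down,1.12
Tahiri,58,hsa-let-7d,down,1.94
Tahiri,58,hsa-miR-99a,down,
Tanic,36,hsa-miR-99a,down,
Tahiri,58,hsa-miR-125b,down,
Tanic,36,hsa-miR-125b,down,
Tahiri,58,hsa-miR-10b,down,
Tanic,36,hsa-miR-10b,down,
Tahiri,58,hsa-miR-100,down,
Tanic,36,hsa-miR-100,down,
Tahiri,58,hsa-miR-205,down,
Tanic,36,hsa-miR-205,down,
Tahiri,58,hsa-miR-195,down,
Tanic,36,hsa-miR-195,down,
Tahiri,58,hsa-miR-130a,down,
Tanic,36,hsa-miR-130a,down,
Tahiri,58,hsa-miR-320c,down,
Tanic,36,hsa-miR-320c,down,
Chen,24,hsa-miR-575,down,
Tahiri,58,hsa-miR-575,down,
Ouyang,6,hsa-miR-486-5p,down,
Tahiri,58,hsa-miR-486-5p,down,
Ouyang,6,hsa-miR-140-3p,down,
Tahiri,58,hsa-miR-140-3p,down,
Tanic,36,hsa-miR-335,down,1.40
Yan,8,hsa-miR-335,down,3.45
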