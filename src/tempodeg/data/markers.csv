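# Glial marker-class gene lists (editable fixture).
# A1/A2/PAN reactive astrocyte panels after Liddelow et al. 2017;
# DAM after Keren-Shaul et al. 2017; reactive oligodendrocyte markers
# as reported for demyelinating injury.
marker_class,gene_id
A1,C3
A1,Fbln5
A1,H2-T23
A1,Serping1
A1,Srgn
A1,H2-D1
A1,Ggta1
A1,Iigp1
A1,Gbp2
A1,Ugt1a1
A1,Fkbp5
A1,Psmb8
A1,Amigo2
A2,Emp1
A2,Ptx3
A2,Tm4sf1
A2,Clcf1
A2,Tgm1
A2,S100a10
A2,Sphk1
A2,Cd109
A2,Ptgs2
A2,Slc10a6
A2,B3gnt5
A2,Cd14
PAN_reactive,Lcn2
PAN_reactive,Steap4
PAN_reactive,S1pr3
PAN_reactive,Timp1
PAN_reactive,Hspb1
PAN_reactive,Cxcl10
PAN_reactive,Cd44
PAN_reactive,Osmr
PAN_reactive,Cp
PAN_reactive,Serpina3n
PAN_reactive,Aspg
PAN_reactive,Vim
PAN_reactive,Gfap
DAM,Apoe
DAM,Axl
DAM,Clec7a
DAM,Tyrobp
DAM,Trem2
DAM,Cst7
DAM,Lpl
DAM,Itgax
DAM,Ctsb
DAM,Ctsd
DAM,Csf1
DAM,Spp1
reactive_oligodendrocyte,C4a
reactive_oligodendrocyte,Serpina3n
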