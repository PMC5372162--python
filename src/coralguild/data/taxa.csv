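taxon_id,genus,label,is_key
AlotL1,Alpheus,A. lottini L1,1
AlotL2,Alpheus,A. lottini L2,1
Alot,Alpheus,A. lottini unresolved,0
Tgut,Trapezia,T. guttata,1
Tsept,Trapezia,T. septata,1
Tspe,Trapezia,T. speciosa,1
Tcymo,Trapezia,T. cymodoce,0
Tser,Trapezia,T. serenei,0
Tbel,Trapezia,T. bella,0
TlutL1,Trapezia,T. lutea L1,0
TlutL2,Trapezia,T. lutea L2,0
TbidL1,Trapezia,T. bidentata L1,0
TbidL2,Trapezia,T. bidentata L2,0
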