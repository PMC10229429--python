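# Synthetic stand-in for a 139-gene immediate-early-gene exclusion list.
# Mix of well-known activity-regulated gene symbols padded with clearly
# synthetic placeholders; replace with a curated list for real data.
Fos
Fosb
Fosl1
Fosl2
Jun
Junb
Jund
Egr1
Egr2
Egr3
Egr4
Nr4a1
Nr4a2
Nr4a3
Arc
Npas4
Dusp1
Dusp4
Dusp5
Dusp6
Dusp14
Homer1
Bdnf
Ier2
Ier3
Ier5
Ier5l
Atf3
Btg1
Btg2
Gadd45a
Gadd45b
Gadd45g
Cyr61
Klf2
Klf4
Klf6
Klf10
Maff
Mafk
Per1
Per2
Sik1
Trib1
Plk2
Ptgs2
Pcsk1
Crem
Nfkbia
Nfkbiz
Rasd1
Sgk1
Tiparp
Midn
Gem
Inhba
Cdkn1a
Csrnp1
Ppp1r15a
Errfi1
Fbxo33
Zfp36
Zfp36l1
Zfp36l2
Socs3
Dnajb5
Scg2
Nptx2
Pim1
Bhlhe40
Bhlhe41
Id2
Id3
Srxn1
Spry2
Spry4
Baz1a
Tnfaip3
Arl4d
Arl5b
Rgs2
Rgs4
Rheb
Vgf
Pcdh8
Syt4
Amigo3
Gpr3
Coq10b
Kdm6b
Peli1
Slc2a3
Sertad1
Rnd3
Plat
Sik2
Nptx1
Penk
Pdyn
Crh
Trib2
Dusp8
Jmjd1c
Egr1os
Fosl1os
SynIeg001
SynIeg002
SynIeg003
SynIeg004
SynIeg005
SynIeg006
SynIeg007
SynIeg008
SynIeg009
SynIeg010
SynIeg011
SynIeg012
SynIeg013
SynIeg014
SynIeg015
SynIeg016
SynIeg017
SynIeg018
SynIeg019
SynIeg020
SynIeg021
SynIeg022
SynIeg023
SynIeg024
SynIeg025
SynIeg026
SynIeg027
SynIeg028
SynIeg029
SynIeg030
SynIeg031
SynIeg032
SynIeg033
SynIeg034
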