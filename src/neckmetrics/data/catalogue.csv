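specimen_id,taxon,clade,category,cervical_count,described_in_english,notes
CM 11338,Camarasaurus lentus,Camarasauridae,complete_described,12,True,juvenile; referred specimen
CM 3018,Apatosaurus louisae,Diplodocidae,complete_described,15,True,holotype; C13-C15 badly crushed and replaced by plaster in the mount
CCG V 20401,Mamenchisaurus hochuanensis,Mamenchisauridae,complete_described,,False,holotype; every vertebra sheared obliquely
ZDM T5402,Shunosaurus lii,Non-neosauropoda,complete_described,,False,referred adult specimen
BYU 9047,Cathetosaurus lewisi,Camarasauridae,complete_described,12,True,holotype; C10-C12 severely damaged
MACN-N 15,Amargasaurus cazaui,Dicraeosauridae,complete_described,,False,holotype; 22 articulated presacrals
ZDM 0083,Mamenchisaurus youngi,Mamenchisauridae,complete_described,,False,holotype
MUCPv-323,Futalognkosaurus dukei,Somphospondyli,complete_described,,True,holotype; neck found in two articulated sections
SSV12001,Xinjiangtitan shanshanesis,Mamenchisauridae,complete_described,,True,holotype
USNM 13786,Camarasaurus lentus,Camarasauridae,complete_undescribed,12,,referred subadult; atlas preserved
MNBH TIG3,Jobaria tiguidensis,Non-neosauropoda,complete_undescribed,12,,holotype; articulated C-shaped neck
SMA 002,Camarasaurus sp.,Camarasauridae,complete_undescribed,,,near-perfect articulation
MAU-Pv-LI-595,Titanosauria indet.,Somphospondyli,complete_undescribed,,,La Invernada titanosaur; known only from an abstract
MAU-Pv-AC-01,Titanosauria indet.,Somphospondyli,complete_undescribed,,,articulated skull to last caudal
MB.R.4886,Dicraeosaurus hansemanni,Dicraeosauridae,missing_atlas,12,False,holotype; complete C2-C12
PMU 233,Euhelopus zdanskyi,Somphospondyli,missing_atlas,17,True,holotype; exemplar a
ZDM T5401,Shunosaurus lii,Non-neosauropoda,missing_atlas,,False,subadult holotype; atlas apparently missing
MCT 1487-R,Titanosauriformes indet.,Somphospondyli,missing_atlas,,True,DGM Series A; 12 cervicals except atlas with three proximal dorsals
GCP-CV-4229,Spinophorosaurus nigerensis,Non-neosauropoda,missing_atlas,13,True,holotype; articulated C2-C13
MOZ-Pv1232,Lavocatisaurus agrioensis,Rebbachisauridae,other_near_complete,,True,complete C1-C11 but possibly not to the last cervical
YPM 1910,Camarasaurus lentus,Camarasauridae,other_near_complete,12,True,holotype; complete from C2 or C3
SMA 0004,Kaatedocus siberi,Diplodocidae,other_near_complete,,True,holotype; C3-C14 preserved
AODF 888,cf. Diamantinasaurus,Somphospondyli,other_near_complete,,True,preserved from C3 or C4
CM 84,Diplodocus carnegii,Diplodocidae,other_near_complete,15,True,holotype; C2-C15 preserved but not all articulated; C11 possibly intrusive
ZDM T5701,Omeisaurus tianfuensis,Mamenchisauridae,other_near_complete,,False,holotype; neck unarticulated and missing about two elements
QJGPM 1001,Qijianglong guokr,Mamenchisauridae,other_near_complete,17,True,holotype; C2-C11 articulated with further cervicals associated
MNBH TIG9,Jobaria tiguidensis,Non-neosauropoda,other_near_complete,12,True,referred; partially articulated axis through mid-dorsals
MNBH TIG6,Jobaria tiguidensis,Non-neosauropoda,other_near_complete,12,,referred subadult; articulated C2-C11
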